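"""End-to-end pipeline: synthetic corpus -> USM -> scores -> EM -> GM ->
refinement -> calibration, plus record filtering.

Every stage writes TSV/FASTA artifacts stamped with the tool version, the
global seed and a config hash; the manifest lists them in dependency
order.  A stage failure raises a :class:`PipelineError` naming the stage,
leaving the artifacts of completed stages on disk.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .calibrate import reconcile_chip
from .design import ProteinDesign
from .evaluator import EMConfig, predict_designs, score_sequences, train_em
from .generator import (
    GMConfig,
    TranslationPair,
    beam_decode,
    stability_weighted_subset,
    train_gm,
)
from .io import config_hash, write_fasta, write_secondary_tsv, write_tsv
from .refine import RefinementConstraints, beam_refine
from .synth import SynthConfig, generate_corpus, make_ladder_chips
from .usm import USMConfig, train_usm

__all__ = ["PipelineConfig", "PipelineError", "filter_by_ci", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    usm: USMConfig = field(default_factory=USMConfig)
    em: Optional[EMConfig] = None          # default: desk scale
    gm: Optional[GMConfig] = None
    ci_max_width: float = 2.0
    n_naturals: int = 200
    n_refine: int = 20                      # designs sent through refinement
    refine_rounds: int = 3
    refine_k: int = 5
    n_generate: int = 10                    # secondary strings to translate
    constraints: RefinementConstraints = field(default_factory=RefinementConstraints)


def filter_by_ci(records: pd.DataFrame, max_width: float = 2.0) -> pd.DataFrame:
    """Keep records whose credible-interval widths are <= *max_width* for
    both proteases; attaches kept/dropped counts as frame attrs."""
    cols = ["trypsin_ci", "chymotrypsin_ci"]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"missing credible-interval columns: {missing}")
    keep = (records[cols] <= max_width).all(axis=1)
    out = records.loc[keep].copy()
    out.attrs["n_kept"] = int(keep.sum())
    out.attrs["n_dropped"] = int((~keep).sum())
    return out


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> Dict[str, str]:
    """Run every stage in dependency order; returns the artifact manifest
    (stage name -> file path)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashed = asdict(config)
    hashed.pop("out_dir", None)  # paths must not perturb the content hash
    stamp = {"seed": config.seed, "config_hash": config_hash(hashed)}
    manifest: Dict[str, str] = {}

    def stage(name):
        def wrap(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise PipelineError(name, exc) from exc
            if verbose:
                print(f"[pipeline] {name} done")
        return wrap

    state: Dict[str, object] = {}

    @stage("synth")
    def _synth():
        synth_cfg = SynthConfig(**{**asdict(config.synth), "seed": config.seed})
        corpus = generate_corpus(synth_cfg, n_naturals=config.n_naturals)
        state["corpus"] = corpus
        write_fasta(corpus["designs"] + corpus["scrambles"], out / "designs.fasta")
        write_secondary_tsv(corpus["designs"], out / "secondary.tsv", stamp)
        write_tsv(corpus["assay"], out / "assay.tsv", stamp)
        write_tsv(corpus["truth"], out / "truth.tsv", stamp)
        manifest["synth"] = str(out / "assay.tsv")

    @stage("filter")
    def _filter():
        kept = filter_by_ci(state["corpus"]["assay"], config.ci_max_width)
        state["assay"] = kept
        write_tsv(kept, out / "assay_filtered.tsv", stamp)
        manifest["filter"] = str(out / "assay_filtered.tsv")

    @stage("train_usm")
    def _usm():
        corpus = state["corpus"]
        assay = state["assay"]
        scr = {}
        for protease in ("trypsin", "chymotrypsin"):
            scr[protease] = [(s.primary, float(assay.loc[s.id, f"{protease}_ec50"]))
                             for s in corpus["scrambles"] if s.id in assay.index]
        usm_cfg = USMConfig(**{**asdict(config.usm), "seed": config.seed})
        state["usm"] = train_usm(scr, usm_cfg)
        manifest["train_usm"] = str(out / "scores.tsv")  # written next stage

    @stage("score")
    def _score():
        corpus, model = state["corpus"], state["usm"]
        assay = state["assay"]
        designs = [d for d in corpus["designs"] if d.id in assay.index]
        state["scored_designs"] = designs
        rows = {}
        for protease in ("trypsin", "chymotrypsin"):
            pred = model.predict([d.primary for d in designs], protease)
            obs = assay.loc[[d.id for d in designs], f"{protease}_ec50"].to_numpy()
            rows[f"{protease}_usm"] = pred
            rows[f"score_{protease}"] = obs - pred
        scores = pd.DataFrame(rows, index=[d.id for d in designs])
        scores["score_min"] = scores[["score_trypsin", "score_chymotrypsin"]].min(axis=1)
        state["scores"] = scores
        write_tsv(scores, out / "scores.tsv", stamp)
        manifest["score"] = str(out / "scores.tsv")

    @stage("train_em")
    def _em():
        em_cfg = config.em or EMConfig.desk_scale(seed=config.seed)
        scores = state["scores"]
        label = {i: (scores.loc[i, "score_chymotrypsin"], scores.loc[i, "score_trypsin"])
                 for i in scores.index}
        model, log = train_em(state["scored_designs"], label, em_cfg,
                              naturals=state["corpus"]["naturals"],
                              verbose=verbose)
        state["em"] = model
        write_tsv(log.set_index("epoch"), out / "em_training_log.tsv", stamp)
        preds = predict_designs(model, state["scored_designs"])
        write_tsv(preds, out / "em_predictions.tsv", stamp)
        manifest["train_em"] = str(out / "em_predictions.tsv")

    @stage("train_gm")
    def _gm():
        gm_cfg = config.gm or GMConfig(iterations=5, seed=config.seed)
        scores = state["scores"]
        subset = stability_weighted_subset(
            state["scored_designs"], dict(scores["score_min"]), seed=config.seed)
        pairs = [TranslationPair(d.secondary, d.primary) for d in subset
                 if "C" not in d.primary]
        model, losses = train_gm(pairs, gm_cfg)
        state["gm"] = model
        manifest["train_gm"] = str(out / "generated.fasta")

    @stage("generate")
    def _generate():
        corpus = state["corpus"]
        rng = np.random.default_rng(config.seed)
        picks = rng.choice(len(corpus["designs"]),
                           size=min(config.n_generate, len(corpus["designs"])),
                           replace=False)
        generated = []
        for j, i in enumerate(picks):
            secondary = corpus["designs"][i].secondary
            for rank, (seq, lp) in enumerate(
                    beam_decode(state["gm"], secondary, width=3)):
                generated.append(ProteinDesign(
                    id=f"gm{j:03d}_{rank}|logp={lp:.3f}", primary=seq,
                    secondary=secondary, provenance="generated"))
        state["generated"] = generated
        write_fasta(generated, out / "generated.fasta")
        manifest["generate"] = str(out / "generated.fasta")

    @stage("refine")
    def _refine():
        model = state["em"]
        scores = state["scores"]
        designs = state["scored_designs"][: config.n_refine]
        rows = []
        for d in designs:
            res = beam_refine(d.primary,
                              lambda seqs: score_sequences(model, seqs),
                              k=config.refine_k, rounds=config.refine_rounds,
                              constraints=config.constraints)
            for rnd, (seq, sc, nsub) in enumerate(
                    zip(res.products, res.scores, res.n_substitutions), start=1):
                rows.append({"id": d.id, "round": rnd, "sequence": seq,
                             "predicted_score": sc, "n_substitutions": nsub})
        refined = pd.DataFrame(rows).set_index("id")
        write_tsv(refined, out / "refined.tsv", stamp)
        manifest["refine"] = str(out / "refined.tsv")

    @stage("calibrate")
    def _calibrate():
        corpus = state["corpus"]
        synth_cfg = corpus["config"]
        chip_a, chip_b, ladder = make_ladder_chips(
            corpus["designs"][:200], synth_cfg, distortion=(1.2, -0.4),
            noise=0.05)
        calibrated, report = reconcile_chip(chip_b, chip_a, ladder)
        write_tsv(calibrated, out / "chip_calibrated.tsv", stamp)
        (out / "calibration_report.json").write_text(json.dumps(report, indent=2))
        manifest["calibrate"] = str(out / "chip_calibrated.tsv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
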