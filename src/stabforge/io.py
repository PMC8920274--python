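"""File formats: FASTA for primary sequences, TSV for everything tabular.

TSV files are UTF-8 and tab-separated with ``#``-prefixed header comment
lines carrying the tool version, the global seed and a config hash, so any
output can be traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .design import ProteinDesign

FASTA_WIDTH = 60


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable config object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_fasta(designs: Sequence[ProteinDesign], path: str | Path) -> None:
    records = [SeqRecord(Seq(d.primary), id=d.id,
                         description=d.provenance) for d in designs]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path, provenance: str = "expert") -> List[ProteinDesign]:
    return [ProteinDesign(id=rec.id, primary=str(rec.seq), provenance=provenance)
            for rec in SeqIO.parse(str(path), "fasta")]


def write_secondary_tsv(designs: Sequence[ProteinDesign], path: str | Path,
                        header: Optional[Dict] = None) -> None:
    df = pd.DataFrame({"id": [d.id for d in designs],
                       "secondary": [d.secondary or "" for d in designs]})
    write_tsv(df.set_index("id"), path, header)


def read_secondary_tsv(path: str | Path) -> Dict[str, str]:
    df = read_tsv(path)
    return dict(zip(df.index, df["secondary"]))


def write_tsv(df: pd.DataFrame, path: str | Path,
              header: Optional[Dict] = None) -> None:
    """Write a DataFrame with '#' metadata comment lines on top."""
    meta = {"tool": f"stabforge {__version__}"}
    meta.update(header or {})
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t")


def read_tsv(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# model checkpoints: a numpy .npz archive holding the weights plus a JSON
# config payload, self-describing enough to rebuild the model

def save_checkpoint(path: str | Path, kind: str, config: Dict,
                    state: Dict) -> None:
    import numpy as np

    meta = json.dumps({"kind": kind, "config": config,
                       "tool": f"stabforge {__version__}"}, default=str)
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path):
    import numpy as np

    archive = np.load(path)
    meta = json.loads(archive["__meta__"].tobytes().decode())
    state = {k: archive[k] for k in archive.files if k != "__meta__"}
    return meta, state
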