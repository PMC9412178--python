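"""File I/O: plain-text formats and atomic writes.

Count matrices are TSV (first column ``gene_id``, one column per sample);
designs are CSV ``sample,subject,condition,group``; qPCR cards are CSV
``subject,gene,condition,replicate,ct`` (empty ct = undetermined well).
"""
from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import pandas as pd

from .containers import PairedCountMatrix, SignaturePanel


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` via a temp file + rename (never a torn file)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_counts(pcm: PairedCountMatrix, counts_path: str | Path, design_path: str | Path) -> None:
    atomic_write_text(counts_path, pcm.counts.to_csv(sep="\t", index_label="gene_id"))
    atomic_write_text(design_path, pcm.design.to_csv(index_label="sample"))


def read_counts(counts_path: str | Path, design_path: str | Path) -> PairedCountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    design = pd.read_csv(design_path, index_col="sample")
    return PairedCountMatrix(counts=counts, design=design)


def write_qpcr_card(card: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, card.to_csv(index=False))


def read_qpcr_card(path: str | Path) -> pd.DataFrame:
    card = pd.read_csv(path)
    required = {"subject", "gene", "condition", "replicate", "ct"}
    missing = required - set(card.columns)
    if missing:
        raise ValueError(f"qPCR card missing columns: {sorted(missing)}")
    return card


def write_panel(panel: SignaturePanel, path: str | Path) -> None:
    atomic_write_text(path, panel.to_json() + "\n")


def read_panel(path: str | Path) -> SignaturePanel:
    return SignaturePanel.from_json(Path(path).read_text())


def write_json(obj, path: str | Path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    from fractions import Fraction

    if isinstance(x, Fraction):
        return float(x)
    try:
        return x.item()  # numpy scalars
    except AttributeError:
        if isinstance(x, (set, tuple)):
            return list(x)
        raise TypeError(f"not JSON serializable: {type(x)}")
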