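"""Readers for the package's TSV interchange formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .expression import CountMatrix


def read_design(path: str | Path) -> pd.Series:
    """Sample -> group mapping from a two-column design TSV."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("design file needs columns sample_id, group")
    return df.set_index("sample_id")["group"]


def read_counts(
    counts_path: str | Path, design: pd.Series
) -> dict[str, CountMatrix]:
    """Per-class count matrices from a combined counts TSV.

    Expected columns: feature_id, rna_class, then one column per sample.
    """
    df = pd.read_csv(counts_path, sep="\t")
    samples = [c for c in df.columns if c not in ("feature_id", "rna_class")]
    out = {}
    for cls, sub in df.groupby("rna_class"):
        counts = sub.set_index("feature_id")[samples]
        out[cls] = CountMatrix(
            counts=counts,
            classes=pd.Series(cls, index=counts.index, name="rna_class"),
            groups=design,
        )
    return out


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"mirna_id", "target_id"} <= set(df.columns):
        raise ValueError("prediction table needs columns mirna_id, target_id")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Feature-by-sample expression matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])
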