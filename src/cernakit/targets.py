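"""miRNA-target interaction building and co-expression filtering.

High-confidence miRNA-target links are the intersection of two independent
predictor tables; the retained links are then restricted to negatively
co-expressed pairs (Spearman rank correlation below a strict threshold,
default -0.7), by default only among differentially expressed miRNAs and
targets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


class InteractionSet:
    """Bidirectional mapping between ceRNA candidates and their miRNAs."""

    def __init__(self, pairs) -> None:
        self._pairs: set[tuple[str, str]] = set()
        self.mirnas_of: dict[str, set[str]] = {}
        self.targets_of: dict[str, set[str]] = {}
        for mirna, target in pairs:
            self._pairs.add((mirna, target))
            self.mirnas_of.setdefault(target, set()).add(mirna)
            self.targets_of.setdefault(mirna, set()).add(target)

    def pairs(self) -> set[tuple[str, str]]:
        return set(self._pairs)

    @property
    def mirna_universe(self) -> set[str]:
        return set(self.targets_of)

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._pairs

    def __eq__(self, other) -> bool:
        return isinstance(other, InteractionSet) and self._pairs == other._pairs

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self._pairs)
        return pd.DataFrame(rows, columns=["mirna_id", "target_id"])


def intersect_predictions(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> InteractionSet:
    """Keep (miRNA, target) pairs predicted by both tools.

    The intersecting results are treated as high-confidence predictions;
    the tool and score columns are dropped.  An empty intersection yields a
    warning, not an error.
    """
    pairs_a = set(zip(table_a["mirna_id"], table_a["target_id"]))
    pairs_b = set(zip(table_b["mirna_id"], table_b["target_id"]))
    common = pairs_a & pairs_b
    if not common:
        warnings.warn("predictor intersection is empty", stacklevel=2)
    return InteractionSet(common)


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson on midranked values.

    Constant input has no defined rank correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for constant input")
    rx = stats.rankdata(x)  # midranks for ties
    ry = stats.rankdata(y)
    return float(stats.pearsonr(rx, ry).statistic)


def pearson(x, y) -> float:
    """Pearson product-moment correlation (constant input raises)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for constant input")
    return float(stats.pearsonr(x, y).statistic)


def negative_coexpression_filter(
    interactions: InteractionSet,
    mirna_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    threshold: float = -0.7,
    de_mirnas: set[str] | None = None,
    de_targets: set[str] | None = None,
    restrict_to_de: bool = True,
) -> tuple[InteractionSet, pd.DataFrame]:
    """Retain interactions with Spearman correlation strictly below threshold.

    Expression frames are features x samples in a consistent sample order.
    With ``restrict_to_de`` (the default) only pairs whose miRNA and target
    are both differentially expressed are considered; other pairs are
    dropped before correlation.  Returns the filtered set and a table of
    the computed correlations for every considered pair.
    """
    if restrict_to_de and (de_mirnas is None or de_targets is None):
        raise ValueError("restrict_to_de requires de_mirnas and de_targets")
    considered = []
    for mirna, target in sorted(interactions.pairs()):
        if restrict_to_de and (mirna not in de_mirnas or target not in de_targets):
            continue
        considered.append((mirna, target))
    missing = sorted(
        {m for m, _ in considered if m not in mirna_expr.index}
        | {t for _, t in considered if t not in target_expr.index}
    )
    if missing:
        raise ValueError(f"missing expression for: {missing[:10]}")
    rows = []
    kept = []
    for mirna, target in considered:
        scc = spearman(
            mirna_expr.loc[mirna].to_numpy(), target_expr.loc[target].to_numpy()
        )
        rows.append((mirna, target, scc))
        if scc < threshold:
            kept.append((mirna, target))
    table = pd.DataFrame(rows, columns=["mirna_id", "target_id", "scc"])
    return InteractionSet(kept), table


def log_normalized(values: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) transform used for all co-expression computations."""
    return np.log2(values + 1.0)
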