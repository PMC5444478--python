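"""Dynamic expression patterns across developmental stages.

A pattern is a sequence of per-transition labels (UP/DOWN/SAME) between
consecutive stages within one genotype; with t time points there are
3^(t-1) - 1 non-constant patterns (the all-SAME sequence is excluded).
The rule-based assignment (significance + sign of each consecutive-stage
contrast) is authoritative; K-means on standardized profiles is a companion
view with a cross-tabulation report.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pattern",
    "enumerate_patterns",
    "assign_pattern",
    "assign_patterns_table",
    "kmeans_profiles",
    "compare_genotype_patterns",
    "NONE_LABEL",
]

TRANSITIONS = ("DOWN", "SAME", "UP")
NONE_LABEL = "NONE"


@dataclass(frozen=True)
class Pattern:
    """A non-constant sequence of UP/DOWN/SAME transitions."""

    transitions: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(t not in TRANSITIONS for t in self.transitions):
            raise ValueError(f"invalid transition in {self.transitions}")
        if all(t == "SAME" for t in self.transitions):
            raise ValueError("the all-SAME sequence is not a pattern")

    @property
    def label(self) -> str:
        return "-".join(self.transitions)

    def reversed(self) -> "Pattern":
        flip = {"UP": "DOWN", "DOWN": "UP", "SAME": "SAME"}
        return Pattern(tuple(flip[t] for t in reversed(self.transitions)))


def enumerate_patterns(t: int) -> list[Pattern]:
    """All 3^(t-1) - 1 non-constant patterns for t time points, lexicographic."""
    if t < 2:
        raise ValueError(f"need at least 2 time points, got t={t}")
    out = []
    for combo in product(TRANSITIONS, repeat=t - 1):
        if all(c == "SAME" for c in combo):
            continue
        out.append(Pattern(combo))
    return out


def assign_pattern(
    transition_results: Sequence[tuple[float, float]],
    fdr: float = 0.05,
    lfc: float = 1.0,
) -> str:
    """Label a gene from its consecutive-stage (q, log2fc) transition results.

    Each transition (later vs earlier stage, log2fc = later - earlier) is
    UP when q < fdr and log2fc >= lfc, DOWN when q < fdr and
    log2fc <= -lfc, else SAME; the all-SAME gene gets NONE.
    """
    if not transition_results:
        raise ValueError("no transition results supplied")
    labels = []
    for q, l2 in transition_results:
        if q < fdr and l2 >= lfc:
            labels.append("UP")
        elif q < fdr and l2 <= -lfc:
            labels.append("DOWN")
        else:
            labels.append("SAME")
    if all(l == "SAME" for l in labels):
        return NONE_LABEL
    return Pattern(tuple(labels)).label


def assign_patterns_table(
    transitions: pd.DataFrame,
    fdr: float = 0.05,
    lfc: float = 1.0,
) -> pd.Series:
    """Vectorized pattern assignment from a long transition table.

    ``transitions`` needs columns gene, transition (orderable label such as
    "25-30"), q_value, log2fc; returns a gene-indexed Series of pattern
    labels (or NONE).
    """
    required = {"gene", "transition", "q_value", "log2fc"}
    missing = required - set(transitions.columns)
    if missing:
        raise ValueError(f"transition table missing column(s) {sorted(missing)}")
    order = sorted(transitions["transition"].unique())
    wide_q = transitions.pivot(index="gene", columns="transition",
                               values="q_value")[order]
    wide_l = transitions.pivot(index="gene", columns="transition",
                               values="log2fc")[order]
    if wide_q.isna().any().any():
        gene = wide_q.index[wide_q.isna().any(axis=1)][0]
        raise ValueError(f"gene {gene!r} is missing a transition result")
    labels = np.full(wide_q.shape, "SAME", dtype=object)
    sig = wide_q.to_numpy() < fdr
    labels[sig & (wide_l.to_numpy() >= lfc)] = "UP"
    labels[sig & (wide_l.to_numpy() <= -lfc)] = "DOWN"
    joined = ["-".join(row) for row in labels]
    flat = "-".join(["SAME"] * len(order))
    return pd.Series(
        [NONE_LABEL if j == flat else j for j in joined],
        index=wide_q.index, name="pattern",
    )


def kmeans_profiles(
    profiles: pd.DataFrame,
    k: int = 8,
    seed: int = 0,
    n_init: int = 25,
) -> pd.Series:
    """K-means (Lloyd, k-means++ init, ``n_init`` restarts) on z-scored profiles.

    ``profiles`` holds per-gene mean log-expression across stages; each row is
    standardized to zero mean / unit sd before clustering, and zero-variance
    genes are excluded. Deterministic given ``seed``.
    """
    from sklearn.cluster import KMeans

    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    Xz = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    if k > Xz.shape[0]:
        raise ValueError(f"k={k} exceeds the {Xz.shape[0]} usable genes")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                algorithm="lloyd", random_state=seed)
    labels = km.fit_predict(Xz)
    return pd.Series(labels, index=profiles.index[keep], name="kmeans_cluster")


def compare_genotype_patterns(
    assign_a: pd.Series, assign_b: pd.Series
) -> dict[str, object]:
    """Per-pattern tallies for two genotypes plus the same-pattern overlap.

    Overlap counts genes carrying an identical non-NONE label in both
    genotypes.
    """
    common = assign_a.index.intersection(assign_b.index)
    a, b = assign_a.loc[common], assign_b.loc[common]
    same = (a == b) & (a != NONE_LABEL)
    tally = pd.DataFrame({
        "n_a": assign_a[assign_a != NONE_LABEL].value_counts(),
        "n_b": assign_b[assign_b != NONE_LABEL].value_counts(),
        "n_same": a[same].value_counts(),
    }).fillna(0).astype(int)
    return {
        "per_pattern": tally.sort_index(),
        "overlap": int(same.sum()),
        "n_assigned_a": int((assign_a != NONE_LABEL).sum()),
        "n_assigned_b": int((assign_b != NONE_LABEL).sum()),
    }
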