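"""Gold-standard-based calibration of the allele-sharing penalty x.

The penalty is tuned on windows centred on experimentally validated
selected variants ("gold standards"): for each window and each x in a grid
(1 <= x <= 4 by default) we compute the fold change between the target's
score and the highest-scoring background SNP in the expected population.
The per-window optimum is the smallest x within a small tolerance of the
maximal fold change (plateau-aware), and the consensus penalty is the
median of the per-window optima.  Complementary diagnostics follow the mean
rank of the targets in the full score ordering and the overlap of top-k
outlier sets across x.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_stats import ScoredVariant

__all__ = [
    "GoldStandardWindow",
    "ConsensusResult",
    "DEFAULT_X_GRID",
    "load_gold_standards",
    "build_windows",
    "rescore_at",
    "fold_change_profile",
    "consensus_penalty",
    "rank_trajectory",
    "top_overlap_across_x",
]

DEFAULT_X_GRID: tuple[float, ...] = tuple(np.arange(1.0, 4.01, 0.25))


@dataclass(frozen=True)
class GoldStandardWindow:
    """A scored window around one validated selected variant."""

    label: str
    target: tuple[str, int]  # (chrom, pos)
    expected_group: str
    variants: tuple[ScoredVariant, ...]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("window is empty")
        if self.target_index() is None:
            raise ValueError(f"target {self.target} absent from window {self.label!r}")

    def target_index(self) -> int | None:
        for i, v in enumerate(self.variants):
            if (v.chrom, v.pos) == self.target:
                return i
        return None


def load_gold_standards() -> pd.DataFrame:
    """The packaged gold-standard table (gene, rsid, GRCh37 chrom/pos,
    derived allele, expected continental group)."""
    with resources.files("finemav.data").joinpath("gold_standards.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def build_windows(
    scored: Sequence[ScoredVariant],
    gold: pd.DataFrame,
    n_snps: int = 1000,
    *,
    mode: str = "snps",
    span_bp: int = 1_000_000,
) -> list[GoldStandardWindow]:
    """Windows centred on each gold-standard variant found in the scores.

    ``mode='snps'`` takes ``n_snps`` SNPs centred on the target (the
    default); ``mode='bp'`` takes all SNPs within ``span_bp/2`` of it.
    Gold standards absent from the score set are skipped.
    """
    if mode not in ("snps", "bp"):
        raise ValueError(f"unknown window mode: {mode!r}")
    by_chrom: dict[str, list[ScoredVariant]] = {}
    for v in sorted(scored, key=lambda v: (v.chrom, v.pos)):
        by_chrom.setdefault(v.chrom, []).append(v)
    windows = []
    for row in gold.itertuples():
        chrom, pos = str(row.chrom), int(row.pos)
        sites = by_chrom.get(chrom, [])
        idx = next((i for i, v in enumerate(sites) if v.pos == pos), None)
        if idx is None:
            continue
        if mode == "snps":
            half = n_snps // 2
            lo = max(0, idx - half)
            sel = sites[lo : lo + n_snps]
        else:
            sel = [v for v in sites if abs(v.pos - pos) <= span_bp // 2]
        windows.append(
            GoldStandardWindow(
                label=f"{row.gene} {row.rsid}",
                target=(chrom, pos),
                expected_group=str(row.group),
                variants=tuple(sel),
            )
        )
    return windows


def rescore_at(variant: ScoredVariant, x: float, group_index: int) -> float:
    """Score a variant at an arbitrary penalty from its stored DAFs.

    Purity is recomputed in frequency mode (f_i = DAF_i / sum DAF); at
    x = 1 the score reduces exactly to DAF * CADD.
    """
    dafs = np.asarray(variant.daf_by_group, dtype=float)
    total = dafs.sum()
    if total <= 0:
        return 0.0
    dap = float(np.power(dafs / total, x).sum())
    return dap * float(dafs[group_index]) * variant.cadd


def fold_change_profile(
    window: GoldStandardWindow,
    x_grid: Sequence[float] = DEFAULT_X_GRID,
    cfg=None,
) -> list[tuple[float, float]]:
    """Fold change target / best background across the penalty grid.

    Returns (x, fold) pairs; the fold is +inf where the background maximum
    is zero (no derived background allele in the expected group).
    """
    gi = window.variants[0].group_labels.index(window.expected_group)
    ti = window.target_index()
    out = []
    for x in x_grid:
        target_score = rescore_at(window.variants[ti], x, gi)
        background = [
            rescore_at(v, x, gi) for i, v in enumerate(window.variants) if i != ti
        ]
        best_bg = max(background, default=0.0)
        fold = np.inf if best_bg == 0 else target_score / best_bg
        out.append((float(x), float(fold)))
    return out


@dataclass(frozen=True)
class ConsensusResult:
    consensus: float
    per_window: tuple[tuple[str, float], ...]  # (label, optimal x)

    @property
    def spread(self) -> tuple[float, float]:
        xs = [x for _, x in self.per_window]
        return (min(xs), max(xs))


def _profile_optimum(
    profile: Sequence[tuple[float, float]], plateau_tol: float
) -> float:
    xs = np.array([x for x, _ in profile])
    folds = np.array([f for _, f in profile])
    order = np.argsort(xs)
    xs, folds = xs[order], folds[order]
    if np.isinf(folds).any():
        return float(xs[np.isinf(folds)][0])  # smallest x achieving the maximum
    best = folds.max()
    ok = folds >= best * (1.0 - plateau_tol)
    return float(xs[ok][0])


def consensus_penalty(
    profiles: "Mapping[str, Sequence[tuple[float, float]]] | Sequence[Sequence[tuple[float, float]]]",
    plateau_tol: float = 0.01,
) -> ConsensusResult:
    """Consensus penalty: median of plateau-aware per-window optima.

    Each per-window optimum is the smallest x whose fold change is within
    ``plateau_tol`` (relative) of the window's maximum; the result is
    invariant to window ordering.
    """
    if isinstance(profiles, Mapping):
        items = list(profiles.items())
    else:
        items = [(f"window_{i}", p) for i, p in enumerate(profiles)]
    if not items:
        raise ValueError("no fold-change profiles given")
    per_window = tuple(
        (label, _profile_optimum(profile, plateau_tol)) for label, profile in items
    )
    consensus = float(np.median([x for _, x in per_window]))
    return ConsensusResult(consensus=consensus, per_window=per_window)


def rank_trajectory(
    targets: Sequence[tuple[str, int, str]],  # (chrom, pos, group)
    scored: Sequence[ScoredVariant],
    x_grid: Sequence[float] = DEFAULT_X_GRID,
) -> list[tuple[float, float]]:
    """Mean rank (1 = best) of the target variants across the penalty grid.

    Each target is ranked within its own group's descending score ordering
    over the full score set (competition ranking: 1 + number of strictly
    higher scores).
    """
    if not scored:
        raise ValueError("empty score set")
    labels = scored[0].group_labels
    key_to_idx = {(v.chrom, v.pos): i for i, v in enumerate(scored)}
    for chrom, pos, _ in targets:
        if (chrom, pos) not in key_to_idx:
            raise ValueError(f"target {(chrom, pos)} absent from the score set")
    out = []
    for x in x_grid:
        ranks = []
        for chrom, pos, group in targets:
            gi = labels.index(group)
            scores = np.array([rescore_at(v, x, gi) for v in scored])
            t = scores[key_to_idx[(chrom, pos)]]
            ranks.append(1 + int((scores > t).sum()))
        out.append((float(x), float(np.mean(ranks))))
    return out


def top_overlap_across_x(
    scores_by_x: Mapping[float, Sequence[tuple[object, float]]], k: int = 100
) -> pd.DataFrame:
    """Pairwise |top-k(x_a) ∩ top-k(x_b)| matrix over penalty values.

    Each entry of ``scores_by_x`` is a list of (variant key, score); the
    diagonal equals min(k, dataset size).  Ties at the k-th score are
    broken by the key to keep the sets deterministic.
    """
    if len(scores_by_x) < 2:
        raise ValueError("need score sets for at least two penalty values")
    tops = {}
    for x, pairs in scores_by_x.items():
        ordered = sorted(pairs, key=lambda kv: (-kv[1], str(kv[0])))
        tops[x] = {key for key, _ in ordered[:k]}
    xs = sorted(tops)
    mat = pd.DataFrame(index=xs, columns=xs, dtype=float)
    for a in xs:
        for b in xs:
            mat.loc[a, b] = len(tops[a] & tops[b])
    return mat
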