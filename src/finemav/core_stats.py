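"""Per-allele statistics for fine-mapping candidate positively selected variants.

The score implemented here combines three allele-specific factors:

``FineMAV_i = DAP * DAF_i * CADD``

* **DAP** (derived allele purity) is a Gini-impurity-like measure of how
  exclusively the derived allele is confined to one of ``n`` population
  groups.  With per-group derived allele counts ``d_i``, shares
  ``f_i = d_i / sum(d)``, and a penalty exponent ``x``::

      DAP = sum_i f_i ** x

  DAP reaches its maximum of 1 when every derived copy falls in a single
  group and decreases as sharing becomes more even (for ``x > 1``).  At
  ``x = 1`` it is identically 1 and the score degenerates to DAF*CADD.
* **DAF_i** is the derived allele frequency in group ``i`` (for continental
  groups: the unweighted mean of the subpopulation DAFs).
* **CADD** is the PHRED-scaled functionality score of the derived
  substitution.

The penalty ``x`` is calibrated for a three-group comparison (``x = 3.5``);
:func:`solve_penalty` converts it to other numbers of groups so that the
purity of a minimally differentiated allele -- equal shares in all groups,
``DAP = n**(1 - x)`` -- is held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UndefinedDAPError",
    "DerivedCounts",
    "PenaltyConfig",
    "ScoredVariant",
    "compute_dap",
    "dap_array",
    "compute_continental_daf",
    "compute_global_daf",
    "compute_finemav",
    "solve_penalty",
    "compute_delta_daf",
    "delta_daf_array",
    "rank_outliers",
]


class UndefinedDAPError(ValueError):
    """Raised when DAP is requested for an allele absent from every group."""


@dataclass(frozen=True)
class DerivedCounts:
    """Per-site derived-allele occurrence across the compared groups.

    Exactly one of ``counts`` (integer copies per group, for equally
    represented groups) or ``frequencies`` (per-group DAF in [0, 1], for
    unequally represented groups) must be given.  In frequency mode the
    shares are ``f_i = DAF_i / sum_j DAF_j``, the direct analogue of the
    count shares.
    """

    counts: tuple[int, ...] | None = None
    frequencies: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if (self.counts is None) == (self.frequencies is None):
            raise ValueError("provide exactly one of counts or frequencies")
        vals = self.counts if self.counts is not None else self.frequencies
        if len(vals) < 2:
            raise ValueError("need at least two population groups")
        if any(v < 0 for v in vals):
            raise ValueError("derived counts/frequencies must be non-negative")
        if self.frequencies is not None and any(f > 1 for f in self.frequencies):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_groups(self) -> int:
        vals = self.counts if self.counts is not None else self.frequencies
        return len(vals)  # type: ignore[arg-type]

    def shares(self) -> np.ndarray:
        """Per-group shares f_i of all derived copies; raises if all-zero."""
        vals = np.asarray(
            self.counts if self.counts is not None else self.frequencies, dtype=float
        )
        total = vals.sum()
        if total <= 0:
            raise UndefinedDAPError(
                "derived allele absent from every group: DAP undefined"
            )
        return vals / total


@dataclass(frozen=True)
class PenaltyConfig:
    """Number of compared groups and the allele-sharing penalty exponent.

    The reference anchor (``reference_n=3``, ``reference_x=3.5``) is the
    calibrated three-continent operating point; :meth:`auto` derives the
    penalty for other group counts from it.
    """

    n: int
    x: float
    reference_n: int = 3
    reference_x: float = 3.5

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two population groups")
        if self.x < 1:
            raise ValueError("penalty x must be >= 1")

    @classmethod
    def auto(cls, n: int, reference_n: int = 3, reference_x: float = 3.5) -> "PenaltyConfig":
        """Config whose x keeps equal-share DAP identical to the reference."""
        return cls(
            n=n,
            x=solve_penalty(n, reference_n, reference_x),
            reference_n=reference_n,
            reference_x=reference_x,
        )


def _as_x(cfg: "PenaltyConfig | float") -> float:
    x = cfg.x if isinstance(cfg, PenaltyConfig) else float(cfg)
    if x < 1:
        raise ValueError("penalty x must be >= 1")
    return x


def compute_dap(counts: "DerivedCounts | Sequence[float]", cfg: "PenaltyConfig | float") -> float:
    """Derived allele purity ``sum_i f_i**x`` for one site.

    Parameters
    ----------
    counts
        :class:`DerivedCounts`, or a plain sequence interpreted as per-group
        derived allele counts.
    cfg
        :class:`PenaltyConfig` or the bare penalty exponent ``x >= 1``.

    Returns
    -------
    float in (0, 1]; equals 1 iff all derived copies fall in a single group.

    Raises
    ------
    UndefinedDAPError
        If the derived allele is absent from every group.
    """
    if not isinstance(counts, DerivedCounts):
        counts = DerivedCounts(counts=tuple(counts))
    x = _as_x(cfg)
    f = counts.shares()
    return float(np.power(f, x).sum())


def dap_array(counts: np.ndarray, x: float, *, undefined: float = np.nan) -> np.ndarray:
    """Vectorised DAP over many sites.

    ``counts`` has shape ``(n_groups, n_sites)`` (derived copies, or
    frequencies for unequally sized groups).  Sites where the derived allele
    is absent everywhere get ``undefined`` (NaN by default).
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = counts / total
        dap = np.power(f, float(x)).sum(axis=0)
    dap[total <= 0] = undefined
    return dap


def compute_continental_daf(
    per_population_dafs: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Continental DAF: unweighted mean of the subpopulation DAFs.

    A sample-size-weighted mean is available by passing ``weights``.
    """
    dafs = np.asarray(per_population_dafs, dtype=float)
    if dafs.size == 0:
        raise ValueError("no subpopulation DAFs given")
    if weights is None:
        return float(dafs.mean())
    return float(np.average(dafs, weights=np.asarray(weights, dtype=float)))


def compute_global_daf(continental_dafs: Sequence[float]) -> float:
    """Global DAF: mean of the continental DAFs (n-dependent by construction)."""
    dafs = np.asarray(continental_dafs, dtype=float)
    if dafs.size == 0:
        raise ValueError("no continental DAFs given")
    return float(dafs.mean())


def compute_finemav(dap: float, daf_i: float, cadd: float) -> float:
    """The per-group score: product DAP * DAF_i * CADD.

    Linear in CADD; zero whenever the derived allele is absent from group i.
    """
    if not (0 <= dap <= 1):
        raise ValueError("dap must lie in [0, 1]")
    if not (0 <= daf_i <= 1):
        raise ValueError("daf must lie in [0, 1]")
    if cadd < 0:
        raise ValueError("cadd must be non-negative")
    return float(dap) * float(daf_i) * float(cadd)


def solve_penalty(n: int, reference_n: int = 3, reference_x: float = 3.5) -> float:
    """Penalty exponent x(n) making scores comparable across group counts.

    An allele shared equally among ``n`` groups has ``DAP = n**(1-x)``.
    Requiring that this floor match the reference anchor,
    ``n**(1-x) = reference_n**(1-reference_x)``, gives the closed form::

        x(n) = 1 + (reference_x - 1) * ln(reference_n) / ln(n)

    e.g. x(2) ~ 4.96 and x(4) ~ 2.98 for the (n=3, x=3.5) anchor.
    """
    if int(n) != n or n < 2:
        raise ValueError("n must be an integer >= 2")
    return 1.0 + (reference_x - 1.0) * math.log(reference_n) / math.log(n)


def compute_delta_daf(
    daf_by_group: Sequence[float], target_group: int, *, method: str = "one_vs_rest"
) -> float:
    """Difference in derived allele frequency for the target group.

    ``one_vs_rest`` (default): DAF of the target minus the mean DAF of all
    other groups.  ``pairwise_max``: the largest pairwise difference, i.e.
    target DAF minus the minimum of the others.
    """
    dafs = np.asarray(daf_by_group, dtype=float)
    if dafs.size < 2:
        raise ValueError("need at least two population groups")
    others = np.delete(dafs, target_group)
    if method == "one_vs_rest":
        return float(dafs[target_group] - others.mean())
    if method == "pairwise_max":
        return float(dafs[target_group] - others.min())
    raise ValueError(f"unknown delta-DAF method: {method!r}")


def delta_daf_array(
    daf: np.ndarray, target_group: int, *, method: str = "one_vs_rest"
) -> np.ndarray:
    """Vectorised delta-DAF over many sites; ``daf`` is (n_groups, n_sites)."""
    daf = np.asarray(daf, dtype=float)
    if daf.shape[0] < 2:
        raise ValueError("need at least two population groups")
    others = np.delete(daf, target_group, axis=0)
    if method == "one_vs_rest":
        return daf[target_group] - others.mean(axis=0)
    if method == "pairwise_max":
        return daf[target_group] - others.min(axis=0)
    raise ValueError(f"unknown delta-DAF method: {method!r}")


@dataclass
class ScoredVariant:
    """A biallelic SNP with its derived allele and all per-group scores."""

    chrom: str
    pos: int
    ref: str
    alt: str
    ancestral: str
    derived: str
    group_labels: tuple[str, ...]
    daf_by_group: tuple[float, ...]
    cadd: float
    dap: float | None = None
    global_daf: float | None = None
    finemav_by_group: tuple[float, ...] = field(default_factory=tuple)
    delta_daf_by_group: tuple[float, ...] = field(default_factory=tuple)
    rsid: str = "."

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def best_group_index(self) -> int:
        """Group with the highest score; score ties (e.g. the single-score
        global-DAF mode) are assigned by delta-DAF."""
        fm = np.asarray(self.finemav_by_group)
        best = np.flatnonzero(fm == fm.max())
        if best.size > 1 and self.delta_daf_by_group:
            dd = np.asarray(self.delta_daf_by_group)[best]
            return int(best[np.argmax(dd)])
        return int(best[0])

    @property
    def best_group(self) -> str:
        return self.group_labels[self.best_group_index]


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (0, c.zfill(3)) if c.isdigit() else (1, c)


def rank_outliers(
    scored: Iterable[ScoredVariant], group: int, top_k: int
) -> list[ScoredVariant]:
    """Top-``top_k`` variants by the group's score, descending.

    Ties are broken by (chromosome, position) ascending so output is
    deterministic.  Returns everything if ``top_k`` exceeds the input size.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ordered = sorted(
        scored,
        key=lambda v: (-v.finemav_by_group[group], _chrom_sort_key(v.chrom), v.pos),
    )
    return ordered[:top_k]
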