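"""Forward-time diploid simulation of a selective sweep in a three-population
model, plus the power / false-discovery-rate evaluation harness.

One replicate is a genomic window of ``n_snps`` loci uniformly spaced over
``window_bp`` base pairs, with a single selected SNP (additive fitness 1,
1+s, 1+2s in one population) and neutral SNPs whose starting derived allele
frequencies are drawn from a beta distribution shared across populations.
The populations then evolve for ``generations`` generations of Wright-Fisher
reproduction with recombination between adjacent loci proportional to their
physical distance and symmetric pairwise migration, after which
``sample_size`` diploid individuals per population are sampled and
per-locus derived allele counts recorded.

Population-size rescaling by a factor lambda (sizes and generation counts
divided by lambda; s, migration and recombination multiplied by lambda)
keeps the products N*s, N*m, N*r and t/N invariant and makes full scenario
grids desk-scale.

Power is measured as the fraction of replicates in which the selected SNP
strictly attains the window maximum of a statistic (delta-DAF, DAPxDAF or
FineMAV) in the selected population; ties count as failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_stats import dap_array, delta_daf_array

__all__ = [
    "DemographicModel",
    "SimulationConfig",
    "CaddModel",
    "SimulatedWindow",
    "PowerRow",
    "PowerTable",
    "OutlierResult",
    "simulate_window",
    "simulate_scenario",
    "assign_cadd",
    "window_statistic",
    "evaluate_top_hit_power",
    "neutral_cutoff",
    "evaluate_outlier_power_fdr",
    "write_windows",
    "read_windows",
]

STATISTICS = ("delta_daf", "dapxdaf", "finemav")


@dataclass(frozen=True)
class DemographicModel:
    """Three-population out-of-Africa model with a two-epoch history.

    The simulation starts ``divergence_gens`` generations before sampling,
    when the African population (first entry of ``names``) and a single
    out-of-Africa (OOA) bottleneck population of size ``ooa_size`` separate
    with shared starting allele frequencies.  ``split_gens`` generations
    before sampling the OOA population splits into the ``ooa_descendants``
    populations, which then exchange migrants pairwise with everybody.
    Setting ``divergence_gens = 0`` collapses the history to a single epoch
    in which all listed populations exist throughout.

    Defaults follow published three-continent estimates: diploid sizes
    14,000 (AFR) and 5,000 (EUR, EAS); an African/non-African divergence
    3,500 generations before sampling with an OOA bottleneck of 1,860; a
    EUR/EAS split 2,000 generations before sampling; and per-generation
    migration of 3e-5 (AFR-EUR), 1.9e-5 (AFR-EAS), 9.6e-5 (EUR-EAS) and
    1.5e-4 (AFR-OOA).  The split is placed before the default selection
    onset (1,000 generations) so that a selected allele establishes in a
    full-sized population -- a structural requirement for any appreciable
    sweep-detection power at s ~ 0.01 when selection starts from DAF 0.01.
    All values are configuration, not contract.
    """

    names: tuple[str, ...] = ("AFR", "EUR", "EAS")
    sizes: tuple[int, ...] = (14000, 5000, 5000)
    # symmetric pairwise migration, keyed in `names` order: (0-1, 0-2, 1-2, ...)
    migration: tuple[float, ...] = (3.0e-5, 1.9e-5, 9.6e-5)
    divergence_gens: int = 3500
    split_gens: int = 2000
    ooa_size: int = 1860
    ooa_migration: float = 1.5e-4
    ooa_descendants: tuple[str, ...] = ("EUR", "EAS")

    def __post_init__(self) -> None:
        n = len(self.names)
        if len(self.sizes) != n:
            raise ValueError("sizes must match names")
        if any(s < 2 for s in self.sizes):
            raise ValueError("population sizes must be >= 2")
        if len(self.migration) != n * (n - 1) // 2:
            raise ValueError("need one migration rate per population pair")
        if any(not (0 <= m < 1) for m in self.migration):
            raise ValueError("migration rates must lie in [0, 1)")
        if self.divergence_gens:
            if self.divergence_gens < self.split_gens:
                raise ValueError("divergence must predate the OOA-descendant split")
            missing = set(self.ooa_descendants) - set(self.names)
            if missing:
                raise ValueError(f"unknown OOA descendants: {sorted(missing)}")
            if len(self.ooa_descendants) < 1:
                raise ValueError("need at least one OOA descendant")

    def migration_matrix(self, scale: float = 1.0) -> np.ndarray:
        """Row-stochastic matrix: row i = source probabilities for pop i."""
        n = len(self.names)
        m = np.zeros((n, n))
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = self.migration[k] * scale
                k += 1
        np.fill_diagonal(m, 1.0 - m.sum(axis=1))
        if (np.diag(m) <= 0).any():
            raise ValueError("rescaled migration rates exceed 1; lower lambda")
        return m

    def index_of(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class SimulationConfig:
    """Window layout, selection regime and sampling design for one scenario."""

    n_snps: int = 1000
    selected_index: int | None = None  # None -> centre of the window
    s: float = 0.0
    selected_start_daf: float = 0.01
    neutral_beta: tuple[float, float] = (0.2, 2.0)
    window_bp: int = 1_000_000
    recomb_per_bp: float = 1e-8
    generations: int = 1000
    sample_size: int = 500
    replicates: int = 100
    selected_pop: str = "EUR"
    rescaling: float = 1.0  # lambda
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not (0 < self.selected_start_daf < 1):
            raise ValueError("selected starting DAF must lie in (0, 1)")
        if self.n_snps < 2:
            raise ValueError("need at least two SNPs per window")
        if self.rescaling < 1:
            raise ValueError("rescaling factor must be >= 1")

    @property
    def selected(self) -> int:
        return self.n_snps // 2 if self.selected_index is None else self.selected_index


@dataclass
class SimulatedWindow:
    """Sampled derived-allele counts for one replicate window."""

    counts: np.ndarray  # (n_pops, n_snps) derived copies in the sample
    n_chrom: tuple[int, ...]  # sampled chromosomes per population
    pop_names: tuple[str, ...]
    selected_index: int
    selected_pop: str
    s: float
    replicate: int = 0
    cadd: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_pops, n_snps = self.counts.shape
        if not (0 <= self.selected_index < n_snps):
            raise ValueError("selected index outside the window")
        for j, nc in enumerate(self.n_chrom):
            if self.counts[j].max(initial=0) > nc:
                raise ValueError("derived count exceeds sampled chromosomes")

    @property
    def daf(self) -> np.ndarray:
        return self.counts / np.asarray(self.n_chrom, dtype=float)[:, None]


def _meiosis(
    haps: np.ndarray, parents: np.ndarray, r_adj: float, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per entry of ``parents`` from the (2N, L) haplotype pool.

    Crossover counts are Binomial(L-1, r_adj) per meiosis; with uniformly
    spaced loci the crossover intervals are uniform without replacement.
    """
    n_gam = parents.size
    n_loci = haps.shape[1]
    start = rng.integers(0, 2, n_gam)
    a_rows = 2 * parents + start
    b_rows = 2 * parents + 1 - start
    gametes = haps[a_rows]  # fancy indexing copies
    n_cx = rng.binomial(n_loci - 1, r_adj, size=n_gam)
    one = np.nonzero(n_cx == 1)[0]
    if one.size:
        # single crossover (the vast majority): uniform cut point, prefix
        # from one parental haplotype, suffix from the other
        cuts = rng.integers(1, n_loci, size=one.size)
        after = np.arange(n_loci) >= cuts[:, None]
        gametes[one] = np.where(after, haps[b_rows[one]], haps[a_rows[one]])
    multi = np.nonzero(n_cx >= 2)[0]
    if multi.size:
        inc = np.zeros((multi.size, n_loci), dtype=np.int8)
        for row, g in enumerate(multi):
            cuts = rng.choice(n_loci - 1, size=n_cx[g], replace=False) + 1
            inc[row, cuts] = 1
        parity = np.cumsum(inc, axis=1) & 1
        gametes[multi] = np.where(parity == 0, haps[a_rows[multi]], haps[b_rows[multi]])
    return gametes


def _sample_parents(
    haps: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
    s: float,
    selected_locus: int | None,
) -> np.ndarray:
    n_ind = haps.shape[0] // 2
    if s == 0 or selected_locus is None:
        return rng.integers(0, n_ind, n_draws)
    dosage = haps[0::2, selected_locus].astype(float) + haps[1::2, selected_locus]
    w = 1.0 + s * dosage  # additive fitness 1, 1+s, 1+2s
    return rng.choice(n_ind, size=n_draws, p=w / w.sum())


def _advance(
    pops: list[np.ndarray],
    sizes: Sequence[int],
    mig: np.ndarray,
    r_adj: float,
    s: float,
    sel_locus: int | None,
    sel_pop: int | None,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """One non-overlapping Wright-Fisher generation for every population."""
    n_pops = len(sizes)
    nxt: list[np.ndarray] = []
    for j in range(n_pops):
        n_off = sizes[j]
        kids = np.empty((2 * n_off, pops[0].shape[1]), dtype=np.uint8)
        src = rng.choice(n_pops, size=n_off, p=mig[j])
        for i in range(n_pops):
            who = np.nonzero(src == i)[0]
            if who.size == 0:
                continue
            sel = sel_locus if i == sel_pop else None
            parents = _sample_parents(pops[i], 2 * who.size, rng, s, sel)
            gam = _meiosis(pops[i], parents, r_adj, rng)
            kids[2 * who] = gam[: who.size]
            kids[2 * who + 1] = gam[who.size :]
        nxt.append(kids)
    return nxt


def simulate_window(
    demography: DemographicModel,
    config: SimulationConfig,
    seed: "int | np.random.SeedSequence",
    replicate: int = 0,
) -> SimulatedWindow:
    """Run one replicate window; a pure function of (configs, seed).

    The history starts at the AFR/OOA divergence (or, without one, at
    ``config.generations`` before sampling) with beta-drawn neutral
    frequencies shared by every population.  The selected locus is reset to
    its starting DAF in every population at selection onset,
    ``config.generations`` generations before sampling, and selection then
    acts on the selected population (or its OOA ancestor before the split).
    Loss of the selected allele before sampling is not an error -- the
    window is still emitted and simply contributes no power.
    """
    rng = np.random.default_rng(seed)
    lam = config.rescaling
    sizes = [max(2, round(n / lam)) for n in demography.sizes]
    sel_gens = max(1, round(config.generations / lam))
    s = config.s * lam
    n_loci = config.n_snps
    spacing = config.window_bp / n_loci
    r_adj = min(0.5, spacing * config.recomb_per_bp * lam)
    sel_locus = config.selected
    sel_pop = demography.index_of(config.selected_pop)

    two_phase = demography.divergence_gens > 0
    if two_phase and config.generations > demography.divergence_gens:
        raise ValueError("selection onset predates the simulated divergence")
    split_gens = (
        max(1, round(demography.split_gens / lam)) if two_phase else sel_gens
    )
    div_gens = (
        max(split_gens, round(demography.divergence_gens / lam))
        if two_phase
        else sel_gens
    )
    onset = sel_gens  # generations before sampling at which selection starts

    a, b = config.neutral_beta
    p0 = rng.beta(a, b, n_loci)
    p0[sel_locus] = config.selected_start_daf

    names = demography.names
    if two_phase:
        ooa_set = set(demography.ooa_descendants)
        mainland = [i for i, nm in enumerate(names) if nm not in ooa_set]
        # phase-1 populations: the persistent ones plus the merged OOA pool
        p1_sizes = [sizes[i] for i in mainland] + [max(2, round(demography.ooa_size / lam))]
        n1 = len(p1_sizes)
        m1 = np.zeros((n1, n1))
        for row in range(n1 - 1):
            m1[row, n1 - 1] = m1[n1 - 1, row] = demography.ooa_migration * lam
        np.fill_diagonal(m1, 1.0 - m1.sum(axis=1))
        pops = [(rng.random((2 * n, n_loci)) < p0).astype(np.uint8) for n in p1_sizes]
        ooa_idx = n1 - 1
        sel_pop_p1 = ooa_idx if names[sel_pop] in ooa_set else mainland.index(sel_pop)
        for t in range(div_gens, split_gens, -1):
            if t == onset:
                for h in pops:
                    h[:, sel_locus] = rng.random(h.shape[0]) < config.selected_start_daf
            selecting = t <= onset and s > 0
            pops = _advance(
                pops, p1_sizes, m1, r_adj, s if selecting else 0.0,
                sel_locus, sel_pop_p1 if selecting else None, rng,
            )
        # OOA split: each descendant population is founded from the OOA pool
        haps = {names[i]: pops[k] for k, i in enumerate(mainland)}
        founders = {}
        for nm in names:
            if nm in ooa_set:
                n = sizes[names.index(nm)]
                parents = _sample_parents(pops[ooa_idx], 2 * n, rng, 0.0, None)
                gam = _meiosis(pops[ooa_idx], parents, r_adj, rng)
                kids = np.empty((2 * n, n_loci), dtype=np.uint8)
                kids[0::2], kids[1::2] = gam[:n], gam[n:]
                founders[nm] = kids
        pops = [founders[nm] if nm in ooa_set else haps[nm] for nm in names]
        remaining = split_gens
    else:
        pops = [(rng.random((2 * n, n_loci)) < p0).astype(np.uint8) for n in sizes]
        remaining = sel_gens

    mig = demography.migration_matrix(scale=lam)
    for t in range(remaining, 0, -1):
        if t == onset:
            for h in pops:
                h[:, sel_locus] = rng.random(h.shape[0]) < config.selected_start_daf
        selecting = t <= onset and s > 0
        pops = _advance(
            pops, sizes, mig, r_adj, s if selecting else 0.0,
            sel_locus, sel_pop if selecting else None, rng,
        )

    counts = np.empty((len(sizes), n_loci), dtype=np.int64)
    n_chrom = []
    for j in range(len(sizes)):
        m = min(config.sample_size, sizes[j])
        idx = rng.choice(sizes[j], size=m, replace=False)
        rows = np.empty(2 * m, dtype=np.int64)
        rows[0::2], rows[1::2] = 2 * idx, 2 * idx + 1
        counts[j] = pops[j][rows].sum(axis=0)
        n_chrom.append(2 * m)

    return SimulatedWindow(
        counts=counts,
        n_chrom=tuple(n_chrom),
        pop_names=demography.names,
        selected_index=sel_locus,
        selected_pop=config.selected_pop,
        s=config.s,
        replicate=replicate,
    )


def simulate_scenario(
    demography: DemographicModel,
    config: SimulationConfig,
    seed: int | None = None,
    replicates: int | None = None,
    cadd_model: "CaddModel | None" = None,
) -> list[SimulatedWindow]:
    """Replicate windows for one scenario, with per-replicate child seeds."""
    reps = config.replicates if replicates is None else replicates
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    children = ss.spawn(2 * reps)  # one stream for the sweep, one for CADD
    out = []
    for r in range(reps):
        w = simulate_window(demography, config, children[2 * r], replicate=r)
        if cadd_model is not None:
            w = assign_cadd(w, cadd_model, children[2 * r + 1])
        out.append(w)
    return out


@dataclass(frozen=True)
class CaddModel:
    """Samplers for per-SNP functionality scores.

    ``neutral`` draws scores for neutral SNPs; the default surrogate is
    Exponential(scale=3.764) truncated at 50, i.e. roughly the PHRED tail
    law P(score > c) = 10^(-c/10) thinned to common derived alleles
    (~7% of draws exceed 10).  ``selected`` draws the selected SNP's score
    from the functional outlier range, uniform on [10.78, 47] by default.
    An empirical mode built from observed score arrays is available via
    :meth:`from_scores`.
    """

    neutral: Callable[[np.random.Generator, int], np.ndarray] = field(
        default=lambda rng, size: np.minimum(rng.exponential(3.764, size), 50.0)
    )
    selected: Callable[[np.random.Generator], float] = field(
        default=lambda rng: float(rng.uniform(10.78, 47.0))
    )
    selected_range: tuple[float, float] = (10.78, 47.0)

    @classmethod
    def from_scores(
        cls,
        neutral_scores: Sequence[float],
        selected_range: tuple[float, float] = (10.78, 47.0),
    ) -> "CaddModel":
        """Empirical neutral sampler resampling an observed score set."""
        pool = np.asarray(neutral_scores, dtype=float)
        if pool.size == 0:
            raise ValueError("empty neutral score pool")
        lo, hi = selected_range
        return cls(
            neutral=lambda rng, size: rng.choice(pool, size=size, replace=True),
            selected=lambda rng: float(rng.uniform(lo, hi)),
            selected_range=selected_range,
        )


def assign_cadd(
    window: SimulatedWindow,
    model: CaddModel,
    seed: "int | np.random.SeedSequence",
) -> SimulatedWindow:
    """Attach functionality scores: neutral sampler everywhere, outlier
    sampler at the selected SNP.  Reproducible from the seed."""
    rng = np.random.default_rng(seed)
    n_loci = window.counts.shape[1]
    cadd = np.asarray(model.neutral(rng, n_loci), dtype=float)
    if cadd.shape != (n_loci,):
        raise ValueError("neutral sampler returned wrong shape")
    if (cadd < 0).any():
        raise ValueError("neutral sampler produced negative scores")
    cadd[window.selected_index] = model.selected(rng)
    return replace(window, cadd=cadd)


def window_statistic(
    window: SimulatedWindow, statistic: str, x: float = 3.5
) -> np.ndarray:
    """Per-locus value of a statistic in the window's selected population.

    Loci where the derived allele is absent from every sample score 0.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    t = window.pop_names.index(window.selected_pop)
    daf = window.daf
    if statistic == "delta_daf":
        return delta_daf_array(daf, t)
    dap = dap_array(window.counts, x, undefined=0.0)
    v = dap * daf[t]
    if statistic == "finemav":
        if window.cadd is None:
            raise ValueError("FineMAV requires CADD scores; run assign_cadd first")
        v = v * window.cadd
    return v


@dataclass(frozen=True)
class PowerRow:
    """Top-hit power of one statistic under one scenario."""

    statistic: str
    x: float
    s: float
    power: float
    replicates: int


@dataclass
class PowerTable:
    rows: list[PowerRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "statistic": r.statistic,
                    "x": r.x,
                    "s": r.s,
                    "power": r.power,
                    "replicates": r.replicates,
                }
                for r in self.rows
            ]
        )

    def to_tsv(self, path: str | Path) -> Path:
        self.to_frame().to_csv(path, sep="\t", index=False)
        return Path(path)


def evaluate_top_hit_power(
    windows: Sequence[SimulatedWindow], statistic: str, x: float = 3.5
) -> PowerRow:
    """Fraction of windows whose selected SNP is the strict window maximum.

    Ties count as failure (conservative).
    """
    if not windows:
        raise ValueError("no windows to evaluate")
    hits = 0
    for w in windows:
        v = window_statistic(w, statistic, x)
        sel = w.selected_index
        rest = np.delete(v, sel)
        if v[sel] > rest.max():
            hits += 1
    return PowerRow(
        statistic=statistic,
        x=x,
        s=windows[0].s,
        power=hits / len(windows),
        replicates=len(windows),
    )


def neutral_cutoff(
    neutral_windows: Sequence[SimulatedWindow],
    x: float = 3.5,
    n_boot: int = 100,
    boot_size: int = 1000,
    seed: int = 0,
) -> float:
    """Upper end of the neutral score distribution via bootstrap.

    Pools FineMAV values from the neutral (s = 0) windows, draws
    ``boot_size`` values with replacement ``n_boot`` times, and returns the
    maximum sampled value across all draws.
    """
    pool = np.concatenate(
        [window_statistic(w, "finemav", x) for w in neutral_windows]
    ) if neutral_windows else np.empty(0)
    if pool.size == 0:
        raise ValueError("empty neutral score pool")
    rng = np.random.default_rng(seed)
    cutoff = -np.inf
    for _ in range(n_boot):
        cutoff = max(cutoff, rng.choice(pool, size=boot_size, replace=True).max())
    return float(cutoff)


@dataclass(frozen=True)
class OutlierResult:
    """Outside-the-neutral-distribution power and FDR at a score cutoff."""

    power: float
    fdr: float
    n_calls: int
    zero_denominator: bool = False


def evaluate_outlier_power_fdr(
    selected_windows: Sequence[SimulatedWindow], cutoff: float, x: float = 3.5
) -> OutlierResult:
    """Power = fraction of selected SNPs scoring above the cutoff; FDR =
    neutral calls / all calls among SNPs above the cutoff."""
    sel_above = 0
    neut_above = 0
    for w in selected_windows:
        v = window_statistic(w, "finemav", x)
        sel = w.selected_index
        sel_above += int(v[sel] > cutoff)
        neut_above += int((np.delete(v, sel) > cutoff).sum())
    n_sel = len(selected_windows)
    if n_sel == 0:
        raise ValueError("no windows to evaluate")
    n_calls = sel_above + neut_above
    if n_calls == 0:
        return OutlierResult(power=0.0, fdr=0.0, n_calls=0, zero_denominator=True)
    return OutlierResult(
        power=sel_above / n_sel, fdr=neut_above / n_calls, n_calls=n_calls
    )


def write_windows(windows: Sequence[SimulatedWindow], path: str | Path) -> Path:
    """Serialise windows as one long-format TSV (gzip if path ends in .gz)."""
    frames = []
    for w in windows:
        n_pops, n_loci = w.counts.shape
        df = pd.DataFrame({"replicate": w.replicate, "locus": np.arange(n_loci)})
        df["selected"] = 0
        df.loc[w.selected_index, "selected"] = 1
        df["cadd"] = w.cadd if w.cadd is not None else np.nan
        for j, name in enumerate(w.pop_names):
            df[f"count_{name}"] = w.counts[j]
            df[f"nchrom_{name}"] = w.n_chrom[j]
        df["s"] = w.s
        df["selected_pop"] = w.selected_pop
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_windows(path: str | Path) -> list[SimulatedWindow]:
    """Inverse of :func:`write_windows`."""
    df = pd.read_csv(path, sep="\t")
    pop_names = tuple(
        c.removeprefix("count_") for c in df.columns if c.startswith("count_")
    )
    windows = []
    for rep, sub in df.groupby("replicate", sort=True):
        sub = sub.sort_values("locus")
        counts = np.stack([sub[f"count_{p}"].to_numpy() for p in pop_names])
        n_chrom = tuple(int(sub[f"nchrom_{p}"].iloc[0]) for p in pop_names)
        cadd_col = sub["cadd"].to_numpy()
        windows.append(
            SimulatedWindow(
                counts=counts,
                n_chrom=n_chrom,
                pop_names=pop_names,
                selected_index=int(sub.loc[sub["selected"] == 1, "locus"].iloc[0]),
                selected_pop=str(sub["selected_pop"].iloc[0]),
                s=float(sub["s"].iloc[0]),
                replicate=int(rep),
                cadd=None if np.isnan(cadd_col).all() else cadd_col,
            )
        )
    return windows
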