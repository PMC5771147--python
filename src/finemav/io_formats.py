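"""Reading variant, panel and functionality-score inputs; writing scored output.

Inputs follow the 1000 Genomes dialects: a VCF with the ancestral allele in
``INFO/AA`` (Ensembl convention, lowercase = low confidence), a panel TSV
with columns ``sample  pop  super_pop``, and a CADD-style tab-separated
score table ``chrom pos ref alt raw phred`` (header lines start with '#',
optionally gzip-compressed).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core_stats import PenaltyConfig, ScoredVariant, compute_global_daf

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationPanel",
    "CaddTable",
    "SkipCounters",
    "SiteCounts",
    "read_sites",
    "VcfSiteReader",
    "read_cadd",
    "score_stream",
    "write_scores",
    "read_scores",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PopulationPanel:
    """Sample -> (population, continental group) assignment."""

    sample_to_pop: dict[str, str]
    sample_to_group: dict[str, str]

    @classmethod
    def from_file(cls, path: str | Path) -> "PopulationPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample", "pop", "super_pop"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"panel file must have columns {sorted(required)}, got {list(df.columns)}"
            )
        if df["sample"].duplicated().any():
            raise ValueError("panel assigns a sample to more than one population")
        return cls(
            sample_to_pop=dict(zip(df["sample"], df["pop"])),
            sample_to_group=dict(zip(df["sample"], df["super_pop"])),
        )

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.sample_to_group.values())))

    def pops_in_group(self, group: str) -> tuple[str, ...]:
        return tuple(
            sorted(
                {p for s, p in self.sample_to_pop.items() if self.sample_to_group[s] == group}
            )
        )


@dataclass
class SkipCounters:
    """Bookkeeping for the streaming scorer's filters.

    emitted + multiallelic + indel + missing_aa + lowercase_aa + no_derived
    + no_cadd equals the number of input records.
    """

    emitted: int = 0
    multiallelic: int = 0
    indel: int = 0
    missing_aa: int = 0
    lowercase_aa: int = 0
    no_derived: int = 0
    no_cadd: int = 0

    def total(self) -> int:
        return (
            self.emitted
            + self.multiallelic
            + self.indel
            + self.missing_aa
            + self.lowercase_aa
            + self.no_derived
            + self.no_cadd
        )

    def summary(self) -> str:
        return (
            f"## sites: emitted={self.emitted} multiallelic={self.multiallelic} "
            f"indel={self.indel} missing_aa={self.missing_aa} "
            f"lowercase_aa={self.lowercase_aa} no_derived={self.no_derived} "
            f"no_cadd={self.no_cadd}"
        )


@dataclass
class SiteCounts:
    """One polarised biallelic SNP with per-group derived counts and DAFs."""

    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str
    ancestral: str
    derived: str
    group_labels: tuple[str, ...]
    derived_counts: tuple[int, ...]  # pooled derived copies per group
    called_counts: tuple[int, ...]  # called chromosomes per group
    daf_by_group: tuple[float, ...]  # continental DAF (mean over subpops)


class VcfSiteReader:
    """Iterate biallelic, ancestrally polarised SNPs of a VCF.

    Yields :class:`SiteCounts`; filter statistics accumulate in ``counters``.
    Sites are skipped when multi-allelic, not a SNP, missing a usable
    ancestral annotation, or (with ``strict_aa``) annotated only in
    lowercase.  Missing genotypes are excluded from DAF denominators;
    haploid calls contribute a single chromosome.
    """

    def __init__(
        self,
        vcf_path: str | Path,
        panel: PopulationPanel,
        groups: Iterable[str] | None = None,
        *,
        strict_aa: bool = False,
        on_extra_sample: str = "warn",
    ) -> None:
        self.vcf = VCF(str(vcf_path), gts012=False)
        self.panel = panel
        self.groups: tuple[str, ...] = tuple(groups) if groups else panel.groups
        self.strict_aa = strict_aa
        self.counters = SkipCounters()

        samples = list(self.vcf.samples)
        extra = [s for s in samples if s not in panel.sample_to_group]
        if extra:
            msg = f"{len(extra)} VCF sample(s) absent from panel (e.g. {extra[0]})"
            if on_extra_sample == "error":
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)

        group_index = {g: i for i, g in enumerate(self.groups)}
        # subpopulations, ordered within their group
        subpops: list[tuple[str, str]] = []
        for g in self.groups:
            for p in self.panel.pops_in_group(g):
                subpops.append((g, p))
        pop_index = {p: i for i, (_, p) in enumerate(subpops)}
        self._subpop_group = np.array([group_index[g] for g, _ in subpops])
        self._n_subpops = len(subpops)
        # per-sample subpop id; -1 = not scored
        idx = np.full(len(samples), -1, dtype=np.int64)
        for i, s in enumerate(samples):
            grp = panel.sample_to_group.get(s)
            if grp in group_index:
                idx[i] = pop_index[panel.sample_to_pop[s]]
        self._sample_subpop = idx
        self._scored_mask = idx >= 0
        for g in self.groups:
            if not any(panel.sample_to_group.get(s) == g for s in samples):
                raise ValueError(f"group {g!r} has no samples in the VCF")

    def __iter__(self) -> Iterator[SiteCounts]:
        c = self.counters
        subpop_of = self._sample_subpop
        for v in self.vcf:
            if len(v.ALT) != 1:
                c.multiallelic += 1
                continue
            ref, alt = v.REF, v.ALT[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                c.indel += 1
                continue
            aa_raw = v.INFO.get("AA")
            aa = str(aa_raw).split("|")[0].strip() if aa_raw is not None else ""
            if not aa or aa == ".":
                c.missing_aa += 1
                continue
            if aa.islower() and self.strict_aa:
                c.lowercase_aa += 1
                continue
            aa = aa.upper()
            if aa not in (ref, alt):
                c.missing_aa += 1
                continue
            derived = alt if aa == ref else ref

            gts = v.genotype.array()
            alleles = gts[:, :-1]  # last column is phasing
            called = alleles >= 0
            is_alt = alleles == 1
            # per-subpopulation chromosome tallies
            weights_called = called.sum(axis=1).astype(float)
            weights_alt = is_alt.sum(axis=1).astype(float)
            called_sub = np.bincount(
                subpop_of[self._scored_mask],
                weights=weights_called[self._scored_mask],
                minlength=self._n_subpops,
            )
            alt_sub = np.bincount(
                subpop_of[self._scored_mask],
                weights=weights_alt[self._scored_mask],
                minlength=self._n_subpops,
            )
            der_sub = alt_sub if derived == alt else called_sub - alt_sub

            with np.errstate(divide="ignore", invalid="ignore"):
                daf_sub = np.where(called_sub > 0, der_sub / called_sub, np.nan)
            n_groups = len(self.groups)
            daf_grp = np.empty(n_groups)
            for gi in range(n_groups):
                sub = daf_sub[self._subpop_group == gi]
                sub = sub[~np.isnan(sub)]
                daf_grp[gi] = sub.mean() if sub.size else 0.0
            der_grp = np.bincount(
                self._subpop_group, weights=der_sub, minlength=n_groups
            )
            called_grp = np.bincount(
                self._subpop_group, weights=called_sub, minlength=n_groups
            )

            if der_grp.sum() == 0:
                c.no_derived += 1
                continue
            c.emitted += 1
            yield SiteCounts(
                chrom=v.CHROM,
                pos=v.POS,
                rsid=v.ID or ".",
                ref=ref,
                alt=alt,
                ancestral=aa,
                derived=derived,
                group_labels=self.groups,
                derived_counts=tuple(int(x) for x in der_grp),
                called_counts=tuple(int(x) for x in called_grp),
                daf_by_group=tuple(float(x) for x in daf_grp),
            )


def read_sites(
    vcf_path: str | Path,
    panel: PopulationPanel,
    groups: Iterable[str] | None = None,
    **kwargs,
) -> VcfSiteReader:
    """Open a VCF for streaming polarised site counts (see VcfSiteReader)."""
    return VcfSiteReader(vcf_path, panel, groups, **kwargs)


class CaddTable:
    """Allele-specific functionality scores keyed by (chrom, pos, ref, alt)."""

    def __init__(self, scores: dict[tuple[str, int, str, str], float] | None = None):
        self._scores = scores or {}

    def __len__(self) -> int:
        return len(self._scores)

    def get(self, chrom: str, pos: int, ref: str, alt: str) -> float | None:
        """Exact lookup; falls back to the swapped allele orientation."""
        hit = self._scores.get((chrom, pos, ref, alt))
        if hit is None:
            hit = self._scores.get((chrom, pos, alt, ref))
        return hit

    def insert_max(self, key: tuple[str, int, str, str], score: float) -> bool:
        """Keep the maximum score for duplicate keys; True if duplicate."""
        old = self._scores.get(key)
        self._scores[key] = score if old is None else max(old, score)
        return old is not None


def read_cadd(tsv_path: str | Path) -> CaddTable:
    """Parse a CADD-style score table into an allele-keyed lookup.

    Columns: chrom, pos, ref, alt, raw, phred; '#' lines are headers.
    Duplicate keys keep the maximum score (logged); an empty file yields an
    empty table with a warning.
    """
    path = Path(tsv_path)
    opener = gzip.open if path.suffix == ".gz" else open
    table = CaddTable()
    duplicates = 0
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"malformed CADD row (need 6 columns): {line!r}")
            chrom, pos, ref, alt = parts[0], parts[1], parts[2], parts[3]
            try:
                phred = float(parts[5])
            except ValueError as exc:
                raise ValueError(f"non-numeric CADD score in row: {line!r}") from exc
            if table.insert_max((chrom, int(pos), ref, alt), phred):
                duplicates += 1
    if duplicates:
        logger.info("read_cadd: %d duplicate keys resolved by max score", duplicates)
    if len(table) == 0:
        warnings.warn(f"CADD table {path} contains no scores", stacklevel=2)
    return table


def score_stream(
    sites: Iterable[SiteCounts],
    cadd: CaddTable,
    cfg: PenaltyConfig,
    daf_mode: str = "continental",
    *,
    counters: SkipCounters | None = None,
) -> Iterator[ScoredVariant]:
    """Join polarised sites with CADD and emit fully scored variants.

    Variants without a CADD entry are skipped (counted in ``counters`` when
    given, which should be the reader's own counter object so the totals
    balance).  ``daf_mode='continental'`` scores each group with its own
    DAF; ``'global'`` computes one score from the mean of the continental
    DAFs (the same value is reported for every group, and the best group is
    the one maximising delta-DAF).
    """
    if daf_mode not in ("continental", "global"):
        raise ValueError(f"unknown daf_mode: {daf_mode!r}")
    for site in sites:
        score = cadd.get(site.chrom, site.pos, site.ref, site.alt)
        if score is None:
            if counters is not None:
                counters.no_cadd += 1
                counters.emitted -= 1
            continue
        dafs = np.asarray(site.daf_by_group)
        total = dafs.sum()
        # frequency-mode purity: robust to unequal group sample sizes
        dap = float(np.power(dafs / total, cfg.x).sum())
        global_daf = compute_global_daf(dafs)
        n = len(dafs)
        delta = tuple(
            float(dafs[i] - np.delete(dafs, i).mean()) for i in range(n)
        )
        if daf_mode == "continental":
            fm = tuple(dap * float(dafs[i]) * score for i in range(n))
        else:
            fm_global = dap * global_daf * score
            fm = tuple(fm_global for _ in range(n))
        yield ScoredVariant(
            chrom=site.chrom,
            pos=site.pos,
            rsid=site.rsid,
            ref=site.ref,
            alt=site.alt,
            ancestral=site.ancestral,
            derived=site.derived,
            group_labels=site.group_labels,
            daf_by_group=site.daf_by_group,
            cadd=score,
            dap=dap,
            global_daf=global_daf,
            finemav_by_group=fm,
            delta_daf_by_group=delta,
        )


def _records_frame(records: Iterable[ScoredVariant]) -> tuple[pd.DataFrame, tuple[str, ...]]:
    records = list(records)
    groups: tuple[str, ...] = records[0].group_labels if records else ()
    rows = []
    for v in records:
        row: dict[str, object] = {
            "chrom": v.chrom,
            "pos": v.pos,
            "rsid": v.rsid,
            "ref": v.ref,
            "alt": v.alt,
            "derived": v.derived,
        }
        for g, d in zip(v.group_labels, v.daf_by_group):
            row[f"daf_{g}"] = d
        row["dap"] = v.dap
        row["cadd"] = v.cadd
        for g, f in zip(v.group_labels, v.finemav_by_group):
            row[f"finemav_{g}"] = f
        row["best_group"] = v.best_group
        rows.append(row)
    cols = ["chrom", "pos", "rsid", "ref", "alt", "derived"]
    cols += [f"daf_{g}" for g in groups] + ["dap", "cadd"]
    cols += [f"finemav_{g}" for g in groups] + ["best_group"]
    return pd.DataFrame(rows, columns=cols if groups else None), groups


_EMPTY_COLUMNS = ["chrom", "pos", "rsid", "ref", "alt", "derived", "dap", "cadd", "best_group"]


def write_scores(
    records: Iterable[ScoredVariant], out_path: str | Path, fmt: str = "tsv"
) -> Path:
    """Write scored variants as a TSV (or BED with the best group's score).

    TSV positions are 1-based; BED intervals are 0-based half-open with the
    best-group score in the score column.  An empty record set yields a
    header-only TSV / empty BED.
    """
    out_path = Path(out_path)
    df, groups = _records_frame(records)
    if fmt == "tsv":
        if df.empty and not groups:
            df = pd.DataFrame(columns=_EMPTY_COLUMNS)
        df.to_csv(out_path, sep="\t", index=False)
    elif fmt == "bed":
        bed = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"] - 1,
                "end": df["pos"],
                "name": df["rsid"].astype(str) + "|" + df["derived"],
                "score": (
                    df[[f"finemav_{g}" for g in groups]].max(axis=1) if groups else []
                ),
            }
        )
        bed.to_csv(out_path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown output format: {fmt!r}")
    return out_path


def read_scores(path: str | Path) -> pd.DataFrame:
    """Re-read a scored TSV produced by :func:`write_scores`."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
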