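"""Synthetic VCF / CADD / panel datasets with planted, closed-form signals.

Genotypes are constructed to hit requested derived allele frequencies
exactly (counts, not sampling), so every planted variant's DAP and FineMAV
are computable in closed form and shipped alongside the files in a truth
table.  Two archetypes are provided: a maximally differentiated allele
(private and fixed in one group, CADD 20 -> score 20 in that group) and a
maximally shared one (fixed everywhere, CADD 45 -> score ~2.89 per group at
x = 3.5).

This module emulates file plumbing only, not population-genetic realism --
that is the simulator's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_stats import PenaltyConfig

__all__ = ["PlantedVariant", "FixtureSpec", "FixturePaths", "make_fixture"]

_BASES = np.array(list("ACGT"))

DEFAULT_GROUPS: dict[str, dict[str, int]] = {
    "AFR": {"AF1": 6, "AF2": 6},
    "EAS": {"EA1": 6, "EA2": 6},
    "EUR": {"EU1": 6, "EU2": 6},
}


@dataclass(frozen=True)
class PlantedVariant:
    """A site whose per-group derived frequency and score are prescribed.

    ``daf`` maps group label -> derived allele frequency, applied to every
    subpopulation of the group (so the continental mean equals it exactly).
    ``ancestral`` is "ref" or "alt": with "alt" the derived allele is the
    VCF REF (polarity flip).
    """

    pos: int
    daf: Mapping[str, float]
    cadd: float
    chrom: str = "1"
    ref: str = "A"
    alt: str = "G"
    ancestral: str = "ref"
    rsid: str = "."

    @classmethod
    def scenario_private_fixed(cls, pos: int, group: str, groups: Sequence[str]) -> "PlantedVariant":
        """Fixed in one group, absent elsewhere, CADD 20 -> FineMAV 20."""
        return cls(pos=pos, daf={g: (1.0 if g == group else 0.0) for g in groups}, cadd=20.0)

    @classmethod
    def scenario_shared_fixed(cls, pos: int, groups: Sequence[str]) -> "PlantedVariant":
        """Fixed in every group, CADD 45 -> FineMAV ~2.89 at n=3, x=3.5."""
        return cls(pos=pos, daf={g: 1.0 for g in groups}, cadd=45.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Layout of a synthetic dataset: samples, planted sites, background."""

    groups: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: DEFAULT_GROUPS
    )
    planted: tuple[PlantedVariant, ...] = ()
    n_background: int = 0
    seed: int = 0
    chrom: str = "1"
    spacing: int = 1000
    cadd_dropout: float = 0.0  # fraction of background sites left out of the table
    penalty: PenaltyConfig | None = None

    def config(self) -> PenaltyConfig:
        return self.penalty or PenaltyConfig(n=len(self.groups), x=3.5)


@dataclass(frozen=True)
class FixturePaths:
    vcf: Path
    cadd: Path
    panel: Path
    truth: Path


def _genotype_block(n_samples: int, derived_copies: int, derived_is_alt: bool) -> str:
    """Deterministic diploid genotype strings realising an exact allele count."""
    if not 0 <= derived_copies <= 2 * n_samples:
        raise ValueError("infeasible derived count for sample size")
    alt_copies = derived_copies if derived_is_alt else 2 * n_samples - derived_copies
    full, rem = divmod(alt_copies, 2)
    gts = ["1/1"] * full + (["0/1"] * rem) + ["0/0"] * (n_samples - full - rem)
    return "\t".join(gts)


def _derived_count(daf: float, n_samples: int) -> int:
    copies = daf * 2 * n_samples
    if abs(copies - round(copies)) > 1e-9:
        raise ValueError(
            f"DAF {daf} is not realisable with {n_samples} diploid samples"
        )
    return int(round(copies))


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixturePaths:
    """Write vcf / cadd.tsv / panel.tsv / truth.tsv under ``out_dir``.

    The truth table holds the closed-form expected continental DAFs, DAP
    (frequency mode) and per-group FineMAV of each planted site at the
    spec's penalty configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    cfg = spec.config()
    groups = list(spec.groups)
    subpops = [(g, p, n) for g in groups for p, n in spec.groups[g].items()]
    sample_names = [
        f"{p}_{i:03d}" for _, p, n in subpops for i in range(n)
    ]

    panel_path = out_dir / "panel.tsv"
    pd.DataFrame(
        {
            "sample": sample_names,
            "pop": [p for _, p, n in subpops for _ in range(n)],
            "super_pop": [g for g, _, n in subpops for _ in range(n)],
        }
    ).to_csv(panel_path, sep="\t", index=False)

    # --- site table -------------------------------------------------------
    planted = sorted(spec.planted, key=lambda v: (v.chrom, v.pos))
    taken = {v.pos for v in planted}
    bg_pos = []
    nxt = spec.spacing
    while len(bg_pos) < spec.n_background:
        if nxt not in taken:
            bg_pos.append(nxt)
        nxt += spec.spacing
    bg_pos = np.asarray(bg_pos, dtype=np.int64)

    vcf_path = out_dir / "sites.vcf"
    cadd_path = out_dir / "cadd.tsv"
    truth_rows = []
    cadd_rows: list[tuple[str, int, str, str, float, float]] = []

    with open(vcf_path, "w") as vcf:
        vcf.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({spec.chrom} | {v.chrom for v in planted}):
            vcf.write(f"##contig=<ID={chrom}>\n")
        vcf.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">\n')
        vcf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        vcf.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )

        rows: list[tuple[int, str]] = []

        for v in planted:
            aa = v.ref if v.ancestral == "ref" else v.alt
            derived = v.alt if v.ancestral == "ref" else v.ref
            derived_is_alt = v.ancestral == "ref"
            blocks = []
            for g, p, n in subpops:
                k = _derived_count(float(v.daf[g]), n)
                blocks.append(_genotype_block(n, k, derived_is_alt))
            line = (
                f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}\t.\t.\tAA={aa}\tGT\t"
                + "\t".join(blocks)
            )
            rows.append((v.pos, line))
            cadd_rows.append((v.chrom, v.pos, v.ref, v.alt, v.cadd / 10.0, v.cadd))

            dafs = np.array([float(v.daf[g]) for g in groups])
            tot = dafs.sum()
            dap = float(np.power(dafs / tot, cfg.x).sum()) if tot > 0 else np.nan
            row: dict[str, object] = {
                "chrom": v.chrom,
                "pos": v.pos,
                "rsid": v.rsid,
                "derived": derived,
                "cadd": v.cadd,
                "dap": dap,
            }
            for g, d in zip(groups, dafs):
                row[f"daf_{g}"] = d
            for g, d in zip(groups, dafs):
                row[f"finemav_{g}"] = dap * d * v.cadd if tot > 0 else 0.0
            truth_rows.append(row)

        if len(bg_pos):
            # vectorised background construction (fast path for large n)
            ref_i = rng.integers(0, 4, len(bg_pos))
            alt_i = (ref_i + rng.integers(1, 4, len(bg_pos))) % 4
            refs, alts = _BASES[ref_i], _BASES[alt_i]
            cadds = np.round(rng.uniform(0.0, 20.0, len(bg_pos)), 3)
            keep_cadd = rng.random(len(bg_pos)) >= spec.cadd_dropout
            counts = {
                (g, p): rng.integers(0, 2 * n + 1, len(bg_pos))
                for g, p, n in subpops
            }
            # memoised genotype strings per (subpop size, count)
            memo: dict[tuple[int, int], str] = {}

            def block(n: int, k: int) -> str:
                key = (n, k)
                if key not in memo:
                    memo[key] = _genotype_block(n, k, True)
                return memo[key]

            chrom = spec.chrom
            for i, pos in enumerate(bg_pos):
                gt = "\t".join(
                    block(n, int(counts[(g, p)][i])) for g, p, n in subpops
                )
                rows.append(
                    (
                        int(pos),
                        f"{chrom}\t{pos}\t.\t{refs[i]}\t{alts[i]}\t.\t.\t"
                        f"AA={refs[i]}\tGT\t{gt}",
                    )
                )
                if keep_cadd[i]:
                    cadd_rows.append(
                        (chrom, int(pos), refs[i], alts[i], cadds[i] / 10.0, cadds[i])
                    )

        rows.sort(key=lambda t: t[0])
        vcf.write("\n".join(line for _, line in rows))
        if rows:
            vcf.write("\n")

    with open(cadd_path, "w") as fh:
        fh.write("## synthetic functionality scores\n")
        fh.write("#Chrom\tPos\tRef\tAlt\tRawScore\tPHRED\n")
        cadd_rows.sort(key=lambda t: t[1])
        fh.write(
            "".join(
                f"{c}\t{p}\t{r}\t{a}\t{raw}\t{ph}\n" for c, p, r, a, raw, ph in cadd_rows
            )
        )

    truth_path = out_dir / "truth.tsv"
    cols = ["chrom", "pos", "rsid", "derived", "cadd", "dap"]
    cols += [f"daf_{g}" for g in groups] + [f"finemav_{g}" for g in groups]
    pd.DataFrame(truth_rows, columns=cols).to_csv(truth_path, sep="\t", index=False)

    return FixturePaths(vcf=vcf_path, cadd=cadd_path, panel=panel_path, truth=truth_path)
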