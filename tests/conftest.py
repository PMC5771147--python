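from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(path: Path, samples: list[str], rows: list[str]) -> Path:
    """Write a minimal VCF from raw data lines (tab-joined strings)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for row in rows:
            fh.write(row + "\n")
    return path


def write_panel(path: Path, triples: list[tuple[str, str, str]]) -> Path:
    with open(path, "w") as fh:
        fh.write("sample\tpop\tsuper_pop\n")
        for s, p, g in triples:
            fh.write(f"{s}\t{p}\t{g}\n")
    return path


@pytest.fixture
def six_sample_panel(tmp_path):
    """Two diploid samples per continental group, one subpopulation each."""
    triples = [
        ("A1", "AFR", "AFR"), ("A2", "AFR", "AFR"),
        ("E1", "EAS", "EAS"), ("E2", "EAS", "EAS"),
        ("U1", "EUR", "EUR"), ("U2", "EUR", "EUR"),
    ]
    return write_panel(tmp_path / "panel.tsv", triples), [t[0] for t in triples]
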