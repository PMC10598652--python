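import textwrap

import numpy as np
import pytest

from svsurv import TrialSimConfig, simulate_trial

VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
    ##INFO=<ID=END,Number=1,Type=Integer,Description="End">
    ##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id(s)">
    ##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##contig=<ID=1>
    ##contig=<ID=9>
    """)


def make_vcf(path, rows, samples=("S1", "S2", "S3")):
    """Write a minimal annotated SV VCF. rows: (chrom,pos,info,genotypes)."""
    lines = [VCF_HEADER.rstrip()]
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        cols += "\tFORMAT\t" + "\t".join(samples)
    lines.append(cols)
    for chrom, pos, info, gts in rows:
        lines.append(
            f"{chrom}\t{pos}\t.\tN\t<DEL>\t.\tPASS\t{info}\tGT\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def tiny_vcf(tmp_path):
    return make_vcf(tmp_path / "tiny.vcf", [
        ("1", 100, "SVTYPE=DEL;END=500;GENE=ENSG00000107290", ["0/1", "0/0", "./."]),
        ("1", 900, "SVTYPE=DUP;END=2000;GENE=ENSG00000107290", ["0/1", "0/0", "0/1"]),
    ])


@pytest.fixture(scope="session")
def sim_trial(tmp_path_factory):
    """One small simulated trial shared across tests (default study conditions)."""
    out = tmp_path_factory.mktemp("trial")
    config = TrialSimConfig(seed=11)
    paths = simulate_trial(config, out)
    return config, paths


def random_survival(rng, n_max=50, tie_prob=0.5):
    """Small random right-censored sample, optionally with ties."""
    n = int(rng.integers(5, n_max + 1))
    t = rng.exponential(5.0, n)
    if rng.random() < tie_prob:
        t = np.ceil(t * 2) / 2  # coarse grid forces ties
    e = (rng.random(n) < 0.7).astype(int)
    if e.sum() == 0:
        e[int(rng.integers(n))] = 1
    return t, e
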