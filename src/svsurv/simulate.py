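"""Two-arm clinical-trial simulator with known genotype and treatment effects.

Generates a matched metadata sheet and gene-annotated multi-sample SV VCF
for a placebo/treatment trial in which some patients carry structural
variants in a target gene.  Event times are exponential with hazard

    lambda_i = lambda0 * exp(bt*arm_i + bc*carrier_i + ba*(age_i - age_mean))

and administrative right-censoring at a fixed study end; the exponential
baseline keeps closed-form survival available for validation.  All draws
come from one seeded generator in patient-index order, so output is
byte-identical across runs with the same config.

The default configuration mirrors the exemplary SETX analysis this package
is built around: 50 patients per arm, carriers concentrated in the
treatment arm (fractions 0.14 placebo / 0.72 treatment, i.e. 7 and 36
expected carriers), every carrier bearing at least three SVs in the target
gene, a beneficial treatment (log-HR -0.7), a deleterious carrier effect
(log-HR +0.5) and a +2%/year age-at-onset effect (log-HR ln 1.02).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["TrialSimConfig", "GroundTruth", "simulate_cohort", "simulate_sv_vcf",
           "simulate_trial", "METADATA_COLUMNS"]

METADATA_COLUMNS = ["patient_ID", "Phenotype", "survival.status_bin", "time", "age_at_onset"]


@dataclass
class TrialSimConfig:
    """Study conditions for one simulated trial."""

    n_placebo: int = 50
    n_treatment: int = 50
    baseline_hazard: float = 0.25          # events per time unit (years)
    log_hr_treatment: float = -0.7
    log_hr_carrier: float = 0.5
    log_hr_age: float = float(np.log(1.02))  # per year of age at onset
    carrier_fraction_placebo: float = 0.14
    carrier_fraction_treatment: float = 0.72
    sv_count_min: int = 3                  # every carrier has at least this many SVs
    sv_count_mu: float = 1.5               # extra counts ~ Poisson(mu)
    age_mean: float = 55.0
    age_sd: float = 10.0
    censor_time: float = 10.0              # administrative cutoff, same unit
    target_gene: str = "ENSG00000107290"   # SETX
    target_symbol: str = "SETX"
    n_decoy_genes: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_placebo < 1 or self.n_treatment < 1:
            raise ValidationError("arm sizes must be >= 1")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be > 0")
        for f in (self.carrier_fraction_placebo, self.carrier_fraction_treatment):
            if not 0 <= f <= 1:
                raise ValidationError("carrier fractions must lie in [0, 1]")
        if self.sv_count_min < 1:
            raise ValidationError("sv_count_min must be >= 1")
        if self.censor_time <= 0:
            raise ValidationError("censor_time must be > 0")


@dataclass
class GroundTruth:
    """Latent per-patient state behind one simulated trial."""

    table: pd.DataFrame  # patient_id, arm, age, carrier, sv_count, latent_time, time, event
    config: TrialSimConfig

    def to_json(self, path) -> None:
        payload = {"config": asdict(self.config),
                   "patients": self.table.to_dict(orient="records")}
        Path(path).write_text(json.dumps(payload, indent=1, default=float) + "\n")


def _truncated_normal(rng, n, mean, sd, lower):
    out = rng.normal(mean, sd, size=n)
    bad = out < lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < lower
    return out


def simulate_cohort(config: TrialSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one trial; returns (metadata sheet, ground-truth ledger).

    The metadata DataFrame uses the column dialect the cohort reader's
    documentation shows: patient_ID, Phenotype (placebo/treatment),
    survival.status_bin (0/1), time, age_at_onset.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    n = c.n_placebo + c.n_treatment
    arm = np.concatenate([np.zeros(c.n_placebo, dtype=int), np.ones(c.n_treatment, dtype=int)])
    frac = np.where(arm == 1, c.carrier_fraction_treatment, c.carrier_fraction_placebo)
    carrier = rng.random(n) < frac
    sv_count = np.where(carrier, c.sv_count_min + rng.poisson(c.sv_count_mu, size=n), 0)
    age = _truncated_normal(rng, n, c.age_mean, c.age_sd, 18.0)
    hazard = c.baseline_hazard * np.exp(
        c.log_hr_treatment * arm + c.log_hr_carrier * carrier.astype(float)
        + c.log_hr_age * (age - c.age_mean))
    latent = rng.exponential(1.0 / hazard)
    time = np.minimum(latent, c.censor_time)
    event = (latent <= c.censor_time).astype(int)

    ids = [f"P{i + 1:04d}" for i in range(n)]
    meta = pd.DataFrame({
        "patient_ID": ids,
        "Phenotype": np.where(arm == 1, "treatment", "placebo"),
        "survival.status_bin": event,
        "time": np.round(time, 6),
        "age_at_onset": np.round(age, 2),
    })
    truth = GroundTruth(table=pd.DataFrame({
        "patient_id": ids, "arm": arm, "age": np.round(age, 2),
        "carrier": carrier, "sv_count": sv_count,
        "latent_time": latent, "time": np.round(time, 6), "event": event,
    }), config=c)
    return meta, truth


def simulate_sv_vcf(config: TrialSimConfig, truth: GroundTruth, path) -> None:
    """Emit a gene-annotated multi-sample VCF consistent with the ground truth.

    Each target-gene SV record is private to one carrier (genotype 0/1 for
    that sample, 0/0 elsewhere), so the tally reproduces sv_count exactly.
    Background SVs in ``n_decoy_genes`` decoy genes are shared across random
    subsets of patients.
    """
    c = config
    rng = np.random.default_rng(c.seed + 1)  # independent of the cohort draws
    tab = truth.table
    samples = list(tab["patient_id"])
    n = len(samples)
    sv_types = np.array(["DEL", "DUP", "INS"])

    lines = []
    pos = 1_000_000
    for i, row in tab.iterrows():
        for _ in range(int(row["sv_count"])):
            svt = str(rng.choice(sv_types))
            length = int(rng.integers(60, 5000))
            gts = ["0/0"] * n
            gts[i] = "0/1"
            lines.append(_vcf_line("9", pos, svt, length, c.target_gene, gts))
            pos += 10_000
    for d in range(c.n_decoy_genes):
        gene = f"ENSG{90000000 + d:011d}"
        chrom = str(d % 22 + 1)
        dpos = 2_000_000
        for _ in range(int(rng.integers(2, 6))):
            svt = str(rng.choice(sv_types))
            length = int(rng.integers(60, 5000))
            carriers = rng.random(n) < 0.3
            gts = ["0/1" if carr else "0/0" for carr in carriers]
            lines.append(_vcf_line(chrom, dpos, svt, length, gene, gts))
            dpos += 10_000

    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Ensembl gene identifier(s)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    header += [f"##contig=<ID={ctg}>" for ctg in [str(i) for i in range(1, 23)]]
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    Path(path).write_text("\n".join(header + lines) + "\n")


def _vcf_line(chrom, pos, svt, length, gene, gts):
    end = pos + (length if svt != "INS" else 0)
    info = f"SVTYPE={svt};END={end};SVLEN={length};GENE={gene}"
    fields = [chrom, str(pos), ".", "N", f"<{svt}>", ".", "PASS", info, "GT"] + gts
    return "\t".join(fields)


def simulate_trial(config: TrialSimConfig, out_dir) -> dict:
    """Write meta.csv, cohort.vcf and truth.json for one simulated trial."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta, truth = simulate_cohort(config)
    meta_path = out / "meta.csv"
    vcf_path = out / "cohort.vcf"
    truth_path = out / "truth.json"
    meta.to_csv(meta_path, index=False, lineterminator="\n")
    simulate_sv_vcf(config, truth, vcf_path)
    truth.to_json(truth_path)
    return {"meta": meta_path, "vcf": vcf_path, "truth": truth_path}
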