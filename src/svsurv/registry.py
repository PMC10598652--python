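"""Disease -> gene panel registry (ClinGen-style gene-disease validity).

The registry is a static, versioned TSV shipped with the package (columns:
disease, gene_symbol, ensembl_gene_id, classification); no network access
ever.  The packaged default covers a few illustrative neurodegenerative
panels (ALS, Charcot-Marie-Tooth, Alzheimer, Parkinson) and is NOT a
clinical resource — supply your own registry file for real analyses.

Disease lookup is case-insensitive and tolerant of unicode dashes, so
"Charcot–Marie–Tooth" (en dashes) matches the packaged
"Charcot-Marie-Tooth" panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError
from .cohort import ClinicalTable
from .tally import GeneTally

__all__ = ["DiseaseGeneRegistry", "load_registry", "disease_summary"]

log = logging.getLogger(__name__)

_REQUIRED = ["disease", "gene_symbol", "ensembl_gene_id", "classification"]


def _norm(name: str) -> str:
    return (name.replace("–", "-").replace("—", "-").replace("‐", "-")
            .strip().casefold())


@dataclass
class DiseaseGeneRegistry:
    """Mapping disease -> list of (gene_symbol, ensembl_gene_id, classification)."""

    entries: dict  # normalized disease name -> DataFrame of panel rows
    display: dict  # normalized name -> original spelling

    @property
    def diseases(self) -> list:
        return sorted(self.display.values())

    def panel(self, disease: str) -> pd.DataFrame:
        key = _norm(disease)
        if key not in self.entries:
            raise ValidationError(
                f"unknown disease {disease!r}; available: {self.diseases}")
        return self.entries[key]


def load_registry(path=None) -> DiseaseGeneRegistry:
    """Load a registry TSV; with no path, the packaged default panels."""
    if path is None:
        with resources.files("svsurv").joinpath("data/disease_genes.tsv").open("rb") as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str)
    else:
        try:
            df = pd.read_csv(Path(path), sep="\t", dtype=str)
        except Exception as exc:
            raise FormatError(f"cannot read registry {path}: {exc}") from exc
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"registry is missing column(s): {missing}")
    if df["ensembl_gene_id"].isna().any() or (df["ensembl_gene_id"].str.len() == 0).any():
        raise FormatError("registry entries must all carry an ensembl_gene_id")

    n0 = len(df)
    df = df.drop_duplicates(subset=["disease", "ensembl_gene_id"]).reset_index(drop=True)
    if len(df) < n0:
        log.warning("registry contained %d duplicate (disease, gene) row(s); deduplicated",
                    n0 - len(df))
    entries, display = {}, {}
    for disease, sub in df.groupby("disease", sort=True):
        key = _norm(disease)
        entries[key] = sub.reset_index(drop=True)
        display[key] = disease
    return DiseaseGeneRegistry(entries=entries, display=display)


def disease_summary(tally: GeneTally, registry: DiseaseGeneRegistry, disease: str,
                    clinical: ClinicalTable) -> pd.DataFrame:
    """Per panel gene: how many trial participants carry >=1 SV, split by arm.

    Genes from the panel that never appear in the VCF annotations get zero
    counts and annotated=False.  Carrier here always means sv_count >= 1
    (the min/max window only applies to stratified survival analyses).
    """
    panel = registry.panel(disease)
    if panel.empty:
        log.warning("disease %r has an empty gene panel", disease)
    ids = clinical.frame["patient_id"]
    arm = clinical.frame.set_index("patient_id")["arm"]
    rows = []
    for _, entry in panel.iterrows():
        gid = entry["ensembl_gene_id"]
        annotated = gid in tally.genes
        counts = tally.gene_counts(gid) if annotated else None
        if annotated:
            carriers = counts.reindex(ids.astype(str)).fillna(0) >= 1
            carriers.index = ids
            n_carr = int(carriers.sum())
            n_plac = int((carriers & (arm == 0)).sum())
            n_trt = int((carriers & (arm == 1)).sum())
        else:
            n_carr = n_plac = n_trt = 0
        rows.append({"gene_symbol": entry["gene_symbol"], "ensembl_gene_id": gid,
                     "classification": entry["classification"], "annotated": annotated,
                     "n_carriers": n_carr, "n_placebo_carriers": n_plac,
                     "n_treatment_carriers": n_trt})
    return pd.DataFrame(rows, columns=["gene_symbol", "ensembl_gene_id", "classification",
                                       "annotated", "n_carriers", "n_placebo_carriers",
                                       "n_treatment_carriers"])
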