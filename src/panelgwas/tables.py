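"""Bundled reference tables.

Two small TSV files ship with the package:

* ``snp_panel.tsv`` — the 39-SNP candidate panel (gene, chromosome,
  1-based position, allele pair, tag flag, per-cohort minor-allele
  frequency and genotyping call rate as percentages).
* ``tagsnp_assoc.tsv`` — the published per-cohort additive-model
  association results for the 26 tag SNPs (effect allele, effect-allele
  frequency, complete-case N, beta in kg/m^2 per allele, SE, t statistic,
  p), for the two cohorts ("PIZARRA", "HORTEGA") and the pooled analysis
  ("POOLED").

These tables serve two roles: they are the *printed inputs* to the
meta-analysis and risk-score selection rules, and they calibrate the
synthetic cohort generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .types import SnpPanel, SnpRecord

COHORTS = ("PIZARRA", "HORTEGA")
POOLED = "POOLED"


def _data_path(name: str):
    return resources.files("panelgwas.data").joinpath(name)


def load_panel_frame() -> pd.DataFrame:
    with resources.as_file(_data_path("snp_panel.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"chromosome": str})
    df["is_tag"] = df["is_tag"].astype(bool)
    return df


def load_panel(tag_only: bool = False) -> SnpPanel:
    """The bundled candidate panel as a :class:`SnpPanel`."""
    df = load_panel_frame()
    if tag_only:
        df = df[df["is_tag"]]
    return SnpPanel(
        SnpRecord(
            snp_id=r.snp_id,
            gene=r.gene,
            chromosome=r.chromosome,
            position=int(r.position),
            allele_a1=r.allele_a1,
            allele_a2=r.allele_a2,
            is_tag=bool(r.is_tag),
        )
        for r in df.itertuples()
    )


def load_tagsnp_assoc() -> pd.DataFrame:
    """Published tag-SNP association table (one row per SNP x analysis)."""
    with resources.as_file(_data_path("tagsnp_assoc.tsv")) as p:
        return pd.read_csv(p, sep="\t")
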