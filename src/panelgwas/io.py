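"""File readers and writers.

Two genotype dialects are supported:

* **PED/MAP** — white-space delimited, six leading PED columns
  (family, individual, father, mother, sex, phenotype) followed by two
  allele columns per SNP; ``0`` is the missing-allele code. The MAP file
  holds ``chromosome  snp_id  cM  position``. The family column doubles
  as the cohort label.
* **tabular** — a TSV with a header row of SNP ids, first column
  ``individual_id``, cells ``0/1/2/NA`` counting copies of the panel's
  ``allele_a1``. Because the matrix itself carries no allele letters, a
  panel is required to interpret it.

On PED input, counts are oriented to the minor allele observed in the
loaded sample unless a panel dictates the count allele. Unknown missing
codes are rejected rather than coerced; alleles outside {A,C,G,T} are a
validation error. Positions are 1-based and no strand flipping happens
at load time.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    VALID_ALLELES,
    GenotypeMatrix,
    PanelError,
    SnpPanel,
    SnpRecord,
    validate_phenotypes,
)


class GenotypeParseError(ValueError):
    """Malformed genotype file; message carries the file and line number."""


def _ped_map_paths(path: str) -> tuple:
    base, ext = os.path.splitext(path)
    if ext in (".ped", ".map"):
        return base + ".ped", base + ".map"
    return path + ".ped", path + ".map"


def read_map(map_path: str) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise GenotypeParseError(
                    f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, snp_id, _cm, pos = parts
            try:
                pos_i = int(pos)
            except ValueError:
                raise GenotypeParseError(
                    f"{map_path}:{lineno}: position {pos!r} is not an integer"
                ) from None
            rows.append((chrom, snp_id, pos_i))
    if not rows:
        raise GenotypeParseError(f"{map_path}: empty MAP file")
    return pd.DataFrame(rows, columns=["chromosome", "snp_id", "position"])


def read_genotypes(
    path: str,
    format: str = "ped_map",
    panel: Optional[SnpPanel] = None,
) -> tuple:
    """Read a genotype file and return ``(GenotypeMatrix, SnpPanel)``.

    For PED/MAP, ``path`` may be the ``.ped`` file or the common prefix.
    If ``panel`` is given its ``allele_a1`` defines the count allele;
    otherwise the sample minor allele is counted and a minimal panel is
    inferred from the data.
    """
    if format == "ped_map":
        return _read_ped_map(path, panel)
    if format == "tabular":
        if panel is None:
            raise PanelError("the tabular dialect requires a panel for allele letters")
        return _read_tabular(path, panel)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_ped_map(path: str, panel: Optional[SnpPanel]):
    ped_path, map_path = _ped_map_paths(path)
    snp_map = read_map(map_path)
    m = len(snp_map)
    ids, cohorts, sexes, allele_rows = [], [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise GenotypeParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"({m} SNPs), got {len(parts)}"
                )
            fid, iid, _pat, _mat, sex, _pheno = parts[:6]
            alleles = parts[6:]
            for a in alleles:
                if a != "0" and a not in VALID_ALLELES:
                    raise GenotypeParseError(
                        f"{ped_path}:{lineno}: invalid allele {a!r}"
                    )
            ids.append(iid)
            cohorts.append(fid)
            sexes.append(sex)
            allele_rows.append(alleles)
    if not ids:
        raise GenotypeParseError(f"{ped_path}: empty PED file")
    if len(set(ids)) != len(ids):
        raise GenotypeParseError(f"{ped_path}: duplicate individual ids")

    alleles_arr = np.array(allele_rows, dtype="U1").reshape(len(ids), m, 2)
    counts = np.full((len(ids), m), np.nan)
    count_allele, other_allele, records = {}, {}, []
    for j, row in enumerate(snp_map.itertuples()):
        a_pair = alleles_arr[:, j, :]
        missing = (a_pair == "0").any(axis=1)
        observed = sorted(set(a_pair[~missing].ravel()))
        if len(observed) > 2:
            raise GenotypeParseError(
                f"{ped_path}: SNP {row.snp_id} has >2 alleles: {observed}"
            )
        if panel is not None and row.snp_id in panel:
            rec = panel[row.snp_id]
            extra = set(observed) - rec.alleles
            if extra:
                raise GenotypeParseError(
                    f"{ped_path}: SNP {row.snp_id} carries alleles {sorted(extra)} "
                    f"absent from the panel pair"
                )
        else:
            if len(observed) == 0:
                # no calls at all: keep a placeholder pair so the matrix stays valid
                a1, a2 = "A", "C"
            elif len(observed) == 1:
                a1 = observed[0]
                a2 = "A" if a1 != "A" else "C"
            else:
                # count the sample minor allele
                n1 = (a_pair == observed[0]).sum()
                n2 = (a_pair == observed[1]).sum()
                a1, a2 = (observed[0], observed[1]) if n1 <= n2 else (observed[1], observed[0])
            rec = SnpRecord(
                snp_id=row.snp_id,
                gene="",
                chromosome=str(row.chromosome),
                position=int(row.position),
                allele_a1=a1,
                allele_a2=a2,
            )
        records.append(rec)
        count_allele[row.snp_id] = rec.allele_a1
        other_allele[row.snp_id] = rec.allele_a2
        counts[~missing, j] = (a_pair[~missing] == rec.allele_a1).sum(axis=1)

    gm = GenotypeMatrix(
        individual_ids=ids,
        snp_ids=list(snp_map["snp_id"]),
        counts=counts,
        count_allele=count_allele,
        other_allele=other_allele,
        cohort=np.array(cohorts, dtype=object),
    )
    return gm, SnpPanel(records)


def _read_tabular(path: str, panel: SnpPanel):
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except pd.errors.EmptyDataError:
        raise GenotypeParseError(f"{path}: empty file") from None
    if df.shape[1] < 2 or df.columns[0] != "individual_id":
        raise GenotypeParseError(
            f"{path}:1: header must start with 'individual_id' followed by snp ids"
        )
    snp_ids = list(df.columns[1:])
    unknown = [s for s in snp_ids if s not in panel]
    if unknown:
        raise GenotypeParseError(f"{path}: SNPs absent from panel: {unknown}")
    counts = df.iloc[:, 1:].to_numpy(dtype=float)
    ok = np.isnan(counts) | np.isin(counts, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise GenotypeParseError(
            f"{path}:{i + 2}: cell {df.iloc[i, j + 1]!r} for {snp_ids[j]} "
            f"is not one of 0/1/2/NA"
        )
    gm = GenotypeMatrix(
        individual_ids=list(df["individual_id"]),
        snp_ids=snp_ids,
        counts=counts,
        count_allele={s: panel[s].allele_a1 for s in snp_ids},
        other_allele={s: panel[s].allele_a2 for s in snp_ids},
    )
    return gm, panel.subset(snp_ids)


def write_genotypes(
    gm: GenotypeMatrix,
    path: str,
    format: str = "ped_map",
    panel: Optional[SnpPanel] = None,
    phenotypes: Optional[pd.DataFrame] = None,
) -> None:
    """Write a genotype matrix in the named dialect.

    For PED output, heterozygotes are written count-allele first and the
    cohort label fills the family column; sex comes from ``phenotypes``
    when provided (1=male, 2=female, 0=unknown).
    """
    if format == "tabular":
        df = gm.to_frame()
        df.insert(0, "individual_id", gm.individual_ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA",
                  float_format="%.0f")
        return
    if format != "ped_map":
        raise ValueError(f"unknown genotype format {format!r}")

    ped_path, map_path = _ped_map_paths(path)
    if panel is None:
        raise PanelError("PED/MAP output requires a panel for chromosome/position")
    sex_code = {}
    if phenotypes is not None:
        sex_code = {
            r.individual_id: {"male": "1", "female": "2"}.get(r.sex, "0")
            for r in phenotypes.itertuples()
        }
    with open(map_path, "w") as fh:
        for s in gm.snp_ids:
            rec = panel[s]
            fh.write(f"{rec.chromosome}\t{s}\t0\t{rec.position}\n")
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(gm.individual_ids):
            fields = [str(gm.cohort[i]), str(iid), "0", "0",
                      sex_code.get(iid, "0"), "-9"]
            for j, s in enumerate(gm.snp_ids):
                c = gm.counts[i, j]
                a1, a2 = gm.count_allele[s], gm.other_allele[s]
                if np.isnan(c):
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [a2, a2]
                elif c == 1:
                    fields += [a1, a2]
                else:
                    fields += [a1, a1]
            fh.write(" ".join(fields) + "\n")


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read a phenotype TSV and validate/derive the obesity flag."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "cohort": str})
    return validate_phenotypes(df)


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False)
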