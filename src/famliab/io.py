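"""Plain-text readers and writers for the cohort, variant and genotype tables.

Formats: tab-separated trio and variant tables, PLINK ``.raw``-style
additive dosage tables, GCTA-style text-triplet GRMs with a companion
``.id`` file, and TSV loading/correlation/uniqueness matrices for factor
models.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from famliab.heritability import GRM
from famliab.psychometrics import FactorModel
from famliab.synthetic_data import GenotypePanel

TRIO_COLUMNS = [
    "family_id",
    "child_id",
    "role",
    "sex",
    "affected",
    "pgs_child",
    "pgs_father",
    "pgs_mother",
    "n_dnm",
    "carrier_class",
    "id_flag",
    "iq_bin",
    "dd_count",
    "age_walk_mo",
    "age_words_mo",
] + [f"pc{i}" for i in range(1, 11)]

VARIANT_COLUMNS = ["individual_id", "gene", "chrom", "consequence", "mpc", "loeuf"]


def write_trios(cohort: pd.DataFrame, path) -> None:
    """Write a trio table with the canonical column order (TSV)."""
    cols = [c for c in TRIO_COLUMNS if c in cohort.columns]
    cohort[cols].to_csv(path, sep="\t", index=False)


def read_trios(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_variants(variants: pd.DataFrame, path) -> None:
    variants[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_raw(panel: GenotypePanel, path) -> None:
    """Write a PLINK ``.raw``-style additive dosage table.

    Columns: FID IID PAT MAT SEX PHENOTYPE then one dosage column per
    SNP, named ``SNP{j}_A``.
    """
    n, m = panel.dosages.shape
    head = pd.DataFrame(
        {
            "FID": panel.ids,
            "IID": panel.ids,
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": panel.phenotype,
        }
    )
    geno = pd.DataFrame(
        panel.dosages.astype(int) if np.allclose(panel.dosages % 1, 0) else panel.dosages,
        columns=[f"SNP{j + 1}_A" for j in range(m)],
    )
    pd.concat([head, geno], axis=1).to_csv(path, sep=" ", index=False)


def read_raw(path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Read a ``.raw`` table; returns (dosages, ids, phenotype)."""
    tab = pd.read_csv(path, sep=r"\s+")
    snp_cols = [c for c in tab.columns if c.endswith("_A")]
    dosages = tab[snp_cols].to_numpy(dtype=float)
    return dosages, tab["IID"].astype(str).tolist(), tab["PHENOTYPE"].to_numpy(dtype=float)


def write_grm(grm: GRM, prefix) -> None:
    """Write a GRM as GCTA text triplets ``i j m value`` plus a ``.grm.id`` file.

    Indices are 1-based over the lower triangle including the diagonal.
    """
    prefix = str(prefix)
    n = grm.values.shape[0]
    with open(prefix + ".grm", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.m}\t{grm.values[i, j]:.8g}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for iid in grm.ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm(prefix) -> GRM:
    prefix = str(prefix)
    ids = [line.split()[1] for line in open(prefix + ".grm.id") if line.strip()]
    n = len(ids)
    values = np.zeros((n, n))
    m = 0
    with open(prefix + ".grm") as fh:
        for line in fh:
            i, j, m_str, val = line.split()
            i, j = int(i) - 1, int(j) - 1
            values[i, j] = values[j, i] = float(val)
            m = int(m_str)
    return GRM(values, ids, m)


def load_factor_model(
    loadings_path,
    phi_path=None,
    theta_path=None,
    general_column: Optional[str] = None,
) -> FactorModel:
    """Assemble a :class:`FactorModel` from TSV matrices with header rows.

    The loadings table has one row per item; ``general_column`` names a
    loading column to peel off as the bifactor general factor.
    """
    loadings = pd.read_csv(loadings_path, sep="\t", index_col=0)
    general = None
    if general_column is not None:
        general = loadings.pop(general_column).to_numpy(dtype=float)
    phi = (
        pd.read_csv(phi_path, sep="\t", index_col=0).to_numpy(dtype=float)
        if phi_path is not None
        else None
    )
    theta = (
        pd.read_csv(theta_path, sep="\t", index_col=0).iloc[:, 0].to_numpy(dtype=float)
        if theta_path is not None
        else None
    )
    return FactorModel(
        loadings.to_numpy(dtype=float), phi=phi, uniquenesses=theta, general=general
    )


def write_cohort_dir(cohort: pd.DataFrame, variants: pd.DataFrame, out_dir) -> None:
    """Write ``trios.tsv``, ``variants.tsv`` and ``dd_genes.txt`` to a directory."""
    from famliab.synthetic_data import dd_gene_list

    out = Path(out_dir)
    os.makedirs(out, exist_ok=True)
    write_trios(cohort, out / "trios.tsv")
    write_variants(variants, out / "variants.tsv")
    with open(out / "dd_genes.txt", "w") as fh:
        fh.write("\n".join(dd_gene_list()) + "\n")
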