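"""High-impact de novo variant classification and carrier assignment.

A de novo variant is *high-impact* when it is protein-truncating (one of a
fixed list of damaging consequences), a missense variant with MPC > 2, or a
structural variant, *and* it falls in a constrained gene (LOEUF < 0.37, the
most-constrained decile), restricted to autosomes when requested.
Thresholds are strict inequalities exactly as conventionally printed:
MPC strictly greater than 2, LOEUF strictly below 0.37.

Individuals are then assigned a carrier class: ``DD`` when at least one
high-impact variant hits a gene from a supplied severe developmental
disorder (DD) gene set, ``nonDD`` when high-impact variants exist only in
other constrained genes, ``none`` otherwise.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Protein-truncating / damaging consequence terms.
DAMAGING_CONSEQUENCES = frozenset(
    {
        "transcript_ablation",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "frameshift_variant",
        "stop_loss",
        "start_loss",
    }
)

#: Full recognized consequence vocabulary.
KNOWN_CONSEQUENCES = DAMAGING_CONSEQUENCES | {
    "missense_variant",
    "structural_variant",
    "other",
}

LOEUF_THRESHOLD = 0.37
MPC_THRESHOLD = 2.0

_AUTOSOMES = frozenset(str(i) for i in range(1, 23))


class UnknownConsequenceError(ValueError):
    """A variant row used a consequence string outside the vocabulary."""

    def __init__(self, rows: Sequence[int], values: Sequence[str]):
        self.rows = list(rows)
        super().__init__(
            f"unknown consequence value(s) {sorted(set(values))} at row index(es) {self.rows}"
        )


def _is_autosome(chrom: pd.Series) -> pd.Series:
    clean = chrom.astype(str).str.replace("chr", "", regex=False)
    return clean.isin(_AUTOSOMES)


def classify_high_impact(
    variants: pd.DataFrame, autosomes_only: bool = True
) -> pd.Series:
    """Flag each annotated variant as high-impact or not.

    Parameters
    ----------
    variants : DataFrame
        Columns ``individual_id, gene, chrom, consequence, mpc, loeuf``.
    autosomes_only : bool
        Restrict high-impact status to autosomal genes (the default).

    Returns
    -------
    Series of bool aligned with ``variants``.  Rows with a missing LOEUF
    annotation can never satisfy the constraint rule; they are excluded
    with a single warning reporting how many were dropped.

    Raises
    ------
    UnknownConsequenceError
        If any consequence string is outside the recognized vocabulary,
        reporting the offending row indices.
    """
    cons = variants["consequence"]
    bad = ~cons.isin(KNOWN_CONSEQUENCES)
    if bad.any():
        raise UnknownConsequenceError(
            variants.index[bad].tolist(), cons[bad].tolist()
        )

    mpc = pd.to_numeric(variants["mpc"], errors="coerce")
    loeuf = pd.to_numeric(variants["loeuf"], errors="coerce")

    damaging = cons.isin(DAMAGING_CONSEQUENCES)
    impactful_missense = (cons == "missense_variant") & (mpc > MPC_THRESHOLD)
    structural = cons == "structural_variant"
    consequence_ok = damaging | impactful_missense | structural

    missing_loeuf = loeuf.isna() & consequence_ok
    if missing_loeuf.any():
        warnings.warn(
            f"{int(missing_loeuf.sum())} variant(s) with a qualifying consequence "
            "lack a LOEUF annotation and were excluded",
            UserWarning,
            stacklevel=2,
        )
    constrained = loeuf < LOEUF_THRESHOLD  # NaN compares False

    flags = consequence_ok & constrained
    if autosomes_only:
        flags &= _is_autosome(variants["chrom"])
    return flags.rename("high_impact")


def assign_carrier_class(
    flags: pd.Series,
    variants: pd.DataFrame,
    dd_gene_set: Iterable[str],
    roster: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Collapse per-variant flags into per-individual carrier classes.

    Parameters
    ----------
    flags : Series of bool
        Output of :func:`classify_high_impact`, aligned with ``variants``.
    variants : DataFrame
        The annotated variant table.
    dd_gene_set : iterable of str
        Gene symbols counted as DD genes; membership of *at least one*
        flagged variant makes the individual a DD carrier.
    roster : sequence of str, optional
        The full cohort roster.  Individuals without any variant receive
        class ``none``; variant carriers absent from the roster raise.

    Returns
    -------
    DataFrame with columns ``individual_id, n_high_impact, carrier_class``.
    """
    dd_genes = set(dd_gene_set)
    tab = variants.loc[flags.to_numpy(), ["individual_id", "gene"]].copy()
    tab["is_dd"] = tab["gene"].isin(dd_genes)
    agg = (
        tab.groupby("individual_id", sort=False)
        .agg(n_high_impact=("gene", "size"), any_dd=("is_dd", "any"))
        .reset_index()
    )

    if roster is not None:
        roster = list(roster)
        present = set(roster)
        missing = sorted(set(variants["individual_id"]) - present)
        if missing:
            raise KeyError(
                f"{len(missing)} individual(s) in the variant table are absent "
                f"from the cohort roster: {missing[:10]}"
            )
        agg = pd.DataFrame({"individual_id": roster}).merge(
            agg, on="individual_id", how="left"
        )
        agg["n_high_impact"] = agg["n_high_impact"].fillna(0).astype(int)
        agg["any_dd"] = agg["any_dd"].astype("boolean").fillna(False).astype(bool)

    agg["carrier_class"] = np.where(
        agg["any_dd"], "DD", np.where(agg["n_high_impact"] > 0, "nonDD", "none")
    )
    return agg[["individual_id", "n_high_impact", "carrier_class"]]


def read_gene_set(path) -> set[str]:
    """Read a gene-set file with one symbol per line (blank lines skipped)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
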