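"""Gene-level promoter methylation and TF activity from DNAm profiles.

A unique promoter methylation value per gene is taken as the average
beta-value over probes within 200 bp of the TSS (class TSS200); when a gene
has no such probes on the array, first-exon probes are used, and failing
that probes 1500 bp upstream of the TSS (TSS1500). The fallback is decided
per gene from probe availability on the array, not per sample. Activity is
then the same binding-profile regression as in expression mode, but on the
sign-reversed network: low promoter methylation accompanies TF binding, so
an active TF shows up as hypomethylation of its activating targets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    ActivityMatrix,
    ProbeAnnotation,
    ProbeMethylationMatrix,
    RegulatoryNetwork,
    REGION_PRIORITY,
)

__all__ = ["assign_gene_dnam", "infer_activity_dnam", "zscore_dnam"]


def assign_gene_dnam(
    betas: ProbeMethylationMatrix, ann: ProbeAnnotation
) -> pd.DataFrame:
    """Collapse probe beta-values to one promoter methylation value per gene.

    Returns a genes x samples DataFrame. Missing beta-values are excluded
    pairwise from the per-gene averages; a gene-sample cell whose informative
    probes are all missing stays NaN. Genes whose probes are all in class
    "Other" are omitted with a warning.
    """
    table = ann.table
    on_array = table[table["probe_id"].isin(betas.values.index)]
    chosen: dict[str, list[str]] = {}
    skipped: list[str] = []
    for gene, sub in on_array.groupby("gene_id", sort=True):
        probes: list[str] = []
        for region in REGION_PRIORITY:
            probes = sub.loc[sub["region_class"] == region, "probe_id"].tolist()
            if probes:
                break
        if probes:
            chosen[gene] = sorted(probes)  # order-independent averaging
        else:
            skipped.append(gene)
    if skipped:
        warnings.warn(
            f"{len(skipped)} genes have no TSS200/FirstExon/TSS1500 probes "
            f"and were omitted (e.g. {skipped[:3]})",
            stacklevel=2,
        )
    if not chosen:
        raise ValueError("no gene has informative promoter probes")
    rows = []
    genes = sorted(chosen)
    for gene in genes:
        block = betas.values.loc[chosen[gene]]
        rows.append(block.mean(axis=0, skipna=True))
    out = pd.DataFrame(rows, index=genes)
    out.index.name = "gene_id"
    return out


def zscore_dnam(gene_dnam: pd.DataFrame, center_only: bool = False) -> pd.DataFrame:
    """Row-wise z-score (or mean-centering) across samples, NaN-aware.

    Uses the sample (ddof=1) standard deviation; zero-variance rows become
    all-zero. Missing cells stay missing and are excluded pairwise both here
    and in the downstream regressions.
    """
    if gene_dnam.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mu = gene_dnam.mean(axis=1, skipna=True)
    centered = gene_dnam.sub(mu, axis=0)
    if center_only:
        return centered
    sd = gene_dnam.std(axis=1, ddof=1, skipna=True)
    flat = sd.fillna(0.0) == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance genes set to all-zero", stacklevel=2
        )
    sd = sd.where(~flat, 1.0)
    z = centered.div(sd, axis=0)
    z.loc[flat] = z.loc[flat].where(z.loc[flat].isna(), 0.0)
    return z


def infer_activity_dnam(
    gene_dnam: pd.DataFrame,
    net: RegulatoryNetwork,
    min_overlap: int = 10,
    center_only: bool = False,
) -> ActivityMatrix:
    """TF x sample activity from gene-level promoter methylation.

    The gene profiles are z-scored across samples, then regressed on the
    binding profiles of the *sign-reversed* network (+1 <-> -1): an active
    TF hypomethylates the promoters of its activating targets, so the
    reversed signs make higher activity come out as a positive t-statistic,
    directly comparable to expression-mode activities.
    """
    from .estimators import TFActivityScorer

    z = zscore_dnam(gene_dnam, center_only=center_only)
    scorer = TFActivityScorer(
        network=net, mode="dnam", min_overlap=min_overlap, assume_standardized=True
    )
    act = scorer.fit_transform(z.T)
    return ActivityMatrix(act.T, mode="dnam")
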