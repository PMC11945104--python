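"""Expression quantification: TPM fold changes and qPCR relative expression.

sRNA differential expression is the plain TPM ratio between conditions
(FC = treatment TPM / control TPM, reported as log2FC at two decimals,
half-up). qPCR relative expression uses the 2^-ddCt method: technical
replicates are averaged within each biological replicate, delta-Ct is the
gene's mean Ct minus the reference gene's mean Ct per biological replicate,
and delta-delta-Ct is taken against a calibrator sample. Heatmap exports use
-ddCt so the calibrator column is exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import round_half_up


@dataclass
class FoldChangeRecord:
    entity_id: str
    tpm_control: float
    tpm_treatment: float
    fc: float
    log2fc: float  # full precision
    log2fc_report: float  # 2 decimals, half-up

    def to_row(self) -> tuple:
        return (self.entity_id, self.tpm_control, self.tpm_treatment,
                self.fc, self.log2fc_report)


@dataclass
class DeltaDeltaCtResult:
    gene: str
    sample: str
    mean_dct: float
    ddct: float
    rel_expr: float  # 2^-ddCt
    neg_ddct: float
    dispersion: float  # SD of per-biological-replicate rel_expr


def log2_fold_change(
    tpm_control: float,
    tpm_treatment: float,
    entity_id: str = "",
    pseudocount: float = 0.0,
) -> FoldChangeRecord:
    """FC = (treatment + pseudocount) / (control + pseudocount) and its log2.

    A zero control TPM with zero pseudocount is an error: pass a pseudocount
    (0.5 is customary) to quantify entities absent from one library.
    """
    c = tpm_control + pseudocount
    t = tpm_treatment + pseudocount
    if c <= 0:
        raise ValueError(
            "control TPM + pseudocount must be positive; supply a pseudocount "
            "(e.g. 0.5) for entities with zero control TPM"
        )
    if t <= 0:
        raise ValueError(
            "treatment TPM + pseudocount must be positive; supply a pseudocount"
        )
    fc = t / c
    lfc = math.log2(fc)
    return FoldChangeRecord(
        entity_id=entity_id, tpm_control=tpm_control, tpm_treatment=tpm_treatment,
        fc=fc, log2fc=lfc, log2fc_report=round_half_up(lfc, 2),
    )


def fold_change_table(tpm: pd.DataFrame, control: str, treatment: str,
                      pseudocount: float = 0.0) -> pd.DataFrame:
    """Vectorized :func:`log2_fold_change` over a TPM table (entities x libraries)."""
    recs = [
        log2_fold_change(row[control], row[treatment], entity_id=str(idx),
                         pseudocount=pseudocount)
        for idx, row in tpm.iterrows()
    ]
    return pd.DataFrame(
        [r.to_row() for r in recs],
        columns=["entity_id", "tpm_control", "tpm_treatment", "fc", "log2fc"],
    )


def delta_delta_ct(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> list[DeltaDeltaCtResult]:
    """Relative expression by the 2^-ddCt method.

    ``ct`` needs columns gene, sample, bio_rep, ct (tech_rep optional;
    technical replicates are averaged first within each biological replicate).
    dCt = mean Ct(gene) - mean Ct(reference) per biological replicate, then
    averaged per sample; ddCt = dCt(sample) - dCt(calibrator);
    rel_expr = 2^-ddCt. Dispersion is the SD of per-replicate rel_expr.
    """
    required = {"gene", "sample", "bio_rep", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    genes = [g for g in ct["gene"].unique() if g != reference_gene]
    samples = list(ct["sample"].unique())
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in the table")

    bio = (
        ct.groupby(["gene", "sample", "bio_rep"], sort=False)["ct"]
        .mean()
        .rename("ct")
        .reset_index()
    )
    ref = bio[bio["gene"] == reference_gene].set_index(["sample", "bio_rep"])["ct"]
    for sample in samples:
        if sample not in ref.index.get_level_values(0):
            raise ValueError(f"reference gene {reference_gene!r} missing in sample {sample!r}")

    results = []
    dct_rep: dict[tuple[str, str], pd.Series] = {}
    for gene in genes:
        sub = bio[bio["gene"] == gene].set_index(["sample", "bio_rep"])["ct"]
        for sample in samples:
            if sample not in sub.index.get_level_values(0):
                continue
            dct_rep[(gene, sample)] = sub.loc[sample] - ref.loc[sample]

    for gene in genes:
        cal = dct_rep.get((gene, calibrator_sample))
        if cal is None:
            raise ValueError(
                f"gene {gene!r} has no Ct values in calibrator sample {calibrator_sample!r}"
            )
        cal_mean = float(cal.mean())
        for sample in samples:
            reps = dct_rep.get((gene, sample))
            if reps is None:
                continue
            mean_dct = float(reps.mean())
            ddct = mean_dct - cal_mean
            rel_reps = np.power(2.0, -(reps.to_numpy() - cal_mean))
            results.append(DeltaDeltaCtResult(
                gene=gene, sample=sample, mean_dct=mean_dct, ddct=ddct,
                rel_expr=2.0 ** (-ddct), neg_ddct=-ddct,
                dispersion=float(np.std(rel_reps, ddof=1)) if len(rel_reps) > 1 else 0.0,
            ))
    return results


def results_to_frame(results: list[DeltaDeltaCtResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene, r.sample, r.mean_dct, r.ddct, r.rel_expr, r.neg_ddct, r.dispersion)
         for r in results],
        columns=["gene", "sample", "mean_dct", "ddct", "rel_expr", "neg_ddct",
                 "dispersion"],
    )


def expression_matrix(
    results: list[DeltaDeltaCtResult],
    genes: list[str] | None = None,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Genes x samples matrix of -ddCt values for heatmap export.

    Missing (gene, sample) combinations are left as NaN and reported, never
    imputed. Returns (matrix, missing combinations).
    """
    df = results_to_frame(results)
    if genes is None:
        genes = list(dict.fromkeys(df["gene"]))
    if samples is None:
        samples = list(dict.fromkeys(df["sample"]))
    mat = pd.DataFrame(np.nan, index=pd.Index(genes, name="gene"),
                       columns=pd.Index(samples, name="sample"))
    for r in results:
        if r.gene in mat.index and r.sample in mat.columns:
            mat.at[r.gene, r.sample] = r.neg_ddct
    missing = [(g, s) for g in genes for s in samples if pd.isna(mat.at[g, s])]
    return mat, missing
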