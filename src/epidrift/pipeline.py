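"""End-to-end orchestration: QC -> EWAS -> SEM calling -> EML association
-> gene burden -> epivariation scan.

`run_pipeline` is the programmatic equivalent of running the CLI stages in
sequence on one cohort; every stage's result is kept on the returned
:class:`PipelineResult` so callers can inspect intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import burden, epivar, ewas, qc, sem
from .cohort import validate_annotation, validate_beta_matrix, validate_sample_sheet

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    beta_qc: pd.DataFrame
    qc_report: qc.QcReport
    pcs: qc.CovariatePCs
    ewas: pd.DataFrame
    bounds: sem.ControlBoundsResult
    calls: sem.SemCalls
    eml: pd.DataFrame
    eml_fit: sem.AssociationFit
    gene_burden: burden.GeneBurdenResult
    window_scan: epivar.WindowScanResult
    regions: pd.DataFrame
    exclusive_genes: pd.DataFrame

    def summary(self) -> str:
        r = self.qc_report
        parts = [
            f"probes: {r.n_input} in, {r.n_retained} after QC "
            f"({', '.join(f'{k}={v}' for k, v in r.removed.items())})",
            f"EWAS: {(self.ewas['q'] < 0.05).sum()} probes at q < 0.05",
            f"SEM calls: {int((self.calls.calls.to_numpy() != 0).sum())} total, "
            f"median per subject {self.eml['global_count'].median():.0f}",
            "Global-EML logit: beta = {:.3f}, p = {:.3g} ({})".format(
                self.eml_fit.params["log_eml"],
                self.eml_fit.pvalues["log_eml"],
                self.eml_fit.method,
            ),
            f"Gene-EML: {len(self.gene_burden.table)} genes tested, "
            f"{(self.gene_burden.table['q'] < 0.05).sum()} at q < 0.05",
            f"epivariations: {len(self.regions)} regions, "
            f"{len(self.exclusive_genes)} case-exclusive genes",
        ]
        return "\n".join(parts)


def run_pipeline(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    annot: pd.DataFrame,
    *,
    burden_B: int = 200,
    window_probes: int = 10,
    alpha: float = 0.05,
    min_sems: int = 3,
    seed: int = 0,
    validate: bool = True,
) -> PipelineResult:
    """Run every analysis stage on one cohort and collect the results."""
    if validate:
        validate_beta_matrix(beta)
        validate_sample_sheet(sheet)
        validate_annotation(annot)

    beta_qc, report = qc.filter_probes(beta, annot)
    pcs = qc.compute_covariate_pcs(sheet)
    ewas_res = ewas.differential_methylation(beta_qc, sheet, pcs)
    bounds = sem.control_bounds(beta_qc, sheet)
    calls = sem.call_sems(beta_qc, bounds)
    eml = sem.global_eml(calls)
    eml_fit = sem.associate_global_eml(eml, sheet, pcs)
    gene_res = burden.gene_burden_scan(
        calls, annot, sheet, pcs, B=burden_B, seed=seed
    )
    scan = epivar.scan_windows(calls, annot.loc[beta_qc.index], window_probes)
    regions = epivar.call_epivariations(
        scan, calls, annot.loc[beta_qc.index], alpha=alpha, min_sems=min_sems
    )
    annotated = epivar.annotate_regions(regions, annot.loc[beta_qc.index])
    exclusive = epivar.case_exclusive_genes(annotated, sheet)
    return PipelineResult(
        beta_qc=beta_qc,
        qc_report=report,
        pcs=pcs,
        ewas=ewas_res,
        bounds=bounds,
        calls=calls,
        eml=eml,
        eml_fit=eml_fit,
        gene_burden=gene_res,
        window_scan=scan,
        regions=regions,
        exclusive_genes=exclusive,
    )
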