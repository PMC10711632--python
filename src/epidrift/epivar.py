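"""Per-subject epivariation detection by sliding-window hypergeometric
enrichment of SEM calls.

For one subject with K SEMs among the N analyzed probes, a window of n
consecutive probes containing k SEMs is scored with the upper cumulative
hypergeometric tail

    p = sum_{j=k}^{min(n, K)} C(K, j) C(N-K, n-j) / C(N, n),

i.e. the chance of drawing at least k of the subject's SEMs into the window
were the SEMs scattered at random over the genome. Windows slide one probe
at a time and never span chromosomes. Significant windows (per-subject
Bonferroni over all windows tested, or a fixed alpha) are merged when they
share probes or abut, trimmed to the first/last SEM they contain, filtered
on a minimum SEM count, and labelled hyper/hypo when at least 80% of their
SEMs agree in direction (otherwise "mixed").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WindowScanResult",
    "hypergeom_tail",
    "scan_windows",
    "call_epivariations",
    "annotate_regions",
    "case_exclusive_genes",
]

WINDOW_COLUMNS = ["subject_id", "chrom", "start_idx", "end_idx", "n", "k", "K", "N", "p"]


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by pmf summation."""
    if k <= 0:
        return 1.0
    hi = min(n, K)
    if k > hi:
        return 0.0
    j = np.arange(k, hi + 1)
    return float(min(1.0, np.sum(stats.hypergeom.pmf(j, N, K, n))))


@dataclass
class WindowScanResult:
    """Sliding-window scan output.

    ``windows`` holds one row per (subject, window) with k >= 1 — windows
    without any SEM have p = 1 by construction and are omitted.
    ``n_windows_tested`` is the per-subject Bonferroni denominator (the
    total number of window positions, identical across subjects);
    ``N`` the genome-wide probe universe; ``skipped_chroms`` chromosomes
    shorter than the window.
    """

    windows: pd.DataFrame
    n_windows_tested: pd.Series
    N: int
    window_probes: int
    skipped_chroms: list[str]


def scan_windows(calls, annot: pd.DataFrame, window_probes: int = 10) -> WindowScanResult:
    """Slide a ``window_probes``-wide window over every chromosome for every
    subject and score SEM enrichment.

    Probes are ordered by (chromosome, position); K and N are genome-wide
    (the subject's total SEM count and the full analyzed probe universe).
    """
    if window_probes < 2:
        raise ValueError("window_probes must be >= 2")
    call_df = calls.calls if hasattr(calls, "calls") else calls
    annot = annot.loc[call_df.index]
    order = annot.sort_values(["chrom", "pos"], kind="stable").index
    call_df = call_df.loc[order]
    annot = annot.loc[order]

    arr = call_df.to_numpy()
    nonzero = (arr != 0).astype(np.int64)
    N = arr.shape[0]
    subjects = call_df.columns
    K_all = nonzero.sum(axis=0)

    chrom_codes = annot["chrom"].to_numpy()
    rows = []
    skipped: list[str] = []
    total_windows = 0
    boundaries = {}
    start = 0
    for chrom in pd.unique(chrom_codes):
        size = int(np.sum(chrom_codes == chrom))
        boundaries[chrom] = (start, start + size)
        start += size

    # per-subject tail lookup cache: p depends only on (K, k)
    tail_cache: dict[tuple[int, int], float] = {}

    for chrom, (lo, hi) in boundaries.items():
        size = hi - lo
        if size < window_probes:
            skipped.append(chrom)
            continue
        n_win = size - window_probes + 1
        total_windows += n_win
        block = nonzero[lo:hi]
        csum = np.vstack([np.zeros((1, block.shape[1]), dtype=np.int64),
                          np.cumsum(block, axis=0)])
        win_counts = csum[window_probes:] - csum[:-window_probes]  # n_win x subjects
        wi, sj = np.nonzero(win_counts)
        for w, j in zip(wi, sj):
            k = int(win_counts[w, j])
            K = int(K_all[j])
            key = (K, k)
            if key not in tail_cache:
                tail_cache[key] = hypergeom_tail(k, N, K, window_probes)
            rows.append(
                (
                    subjects[j],
                    chrom,
                    lo + w,
                    lo + w + window_probes - 1,
                    window_probes,
                    k,
                    K,
                    N,
                    tail_cache[key],
                )
            )
    windows = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    n_tested = pd.Series(total_windows, index=subjects, name="n_windows_tested")
    return WindowScanResult(
        windows=windows,
        n_windows_tested=n_tested,
        N=N,
        window_probes=window_probes,
        skipped_chroms=skipped,
    )


def call_epivariations(
    scan: WindowScanResult,
    calls,
    annot: pd.DataFrame,
    *,
    alpha: float = 0.05,
    min_sems: int = 3,
    correction: str = "bonferroni",
    direction_threshold: float = 0.8,
) -> pd.DataFrame:
    """Merge significant windows into per-subject epivariation regions.

    The significance cut-off is ``alpha / n_windows_tested`` per subject
    (``correction="bonferroni"``, default) or the fixed ``alpha``
    (``correction="none"``). Overlapping or abutting significant windows are
    merged; each merged span is trimmed to the first and last SEM-carrying
    probe it contains and must hold at least ``min_sems`` SEM calls.

    Returns a frame with subject_id, chrom, start/end (bp), start_idx/
    end_idx (probe indices in scan order), n_probes, n_sems, direction and
    min_window_p.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    call_df = calls.calls if hasattr(calls, "calls") else calls
    annot = annot.loc[call_df.index]
    order = annot.sort_values(["chrom", "pos"], kind="stable").index
    call_df = call_df.loc[order]
    annot = annot.loc[order]
    pos = annot["pos"].to_numpy()
    arr = call_df.to_numpy()

    regions = []
    wins = scan.windows
    for subject, sub in wins.groupby("subject_id", sort=False):
        cutoff = alpha / scan.n_windows_tested[subject] if correction == "bonferroni" else alpha
        sig = sub[sub["p"] < cutoff]
        if sig.empty:
            continue
        j = call_df.columns.get_loc(subject)
        col = arr[:, j]
        for chrom, chrom_wins in sig.groupby("chrom", sort=False):
            iv = chrom_wins.sort_values("start_idx")
            cur_s, cur_e, cur_p = None, None, 1.0
            merged = []
            for _, row in iv.iterrows():
                s, e, p = int(row["start_idx"]), int(row["end_idx"]), float(row["p"])
                if cur_s is None:
                    cur_s, cur_e, cur_p = s, e, p
                elif s <= cur_e + 1:  # overlapping or abutting
                    cur_e = max(cur_e, e)
                    cur_p = min(cur_p, p)
                else:
                    merged.append((cur_s, cur_e, cur_p))
                    cur_s, cur_e, cur_p = s, e, p
            merged.append((cur_s, cur_e, cur_p))
            for s, e, p in merged:
                sem_idx = np.nonzero(col[s:e + 1])[0]
                if sem_idx.size < min_sems:
                    continue
                s2, e2 = s + int(sem_idx[0]), s + int(sem_idx[-1])
                sems = col[s2:e2 + 1]
                n_hyper = int(np.sum(sems > 0))
                n_hypo = int(np.sum(sems < 0))
                total = n_hyper + n_hypo
                if n_hyper / total >= direction_threshold:
                    direction = "hyper"
                elif n_hypo / total >= direction_threshold:
                    direction = "hypo"
                else:
                    direction = "mixed"
                regions.append(
                    {
                        "subject_id": subject,
                        "chrom": chrom,
                        "start": int(pos[s2]),
                        "end": int(pos[e2]),
                        "start_idx": s2,
                        "end_idx": e2,
                        "n_probes": e2 - s2 + 1,
                        "n_sems": total,
                        "direction": direction,
                        "min_window_p": p,
                    }
                )
    cols = ["subject_id", "chrom", "start", "end", "start_idx", "end_idx",
            "n_probes", "n_sems", "direction", "min_window_p"]
    return pd.DataFrame(regions, columns=cols)


def annotate_regions(regions: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """Map each region to every gene with a probe inside its span.

    Returns one row per (region, gene); intergenic regions are kept with an
    empty gene so no region silently disappears.
    """
    annot = annot.sort_values(["chrom", "pos"], kind="stable")
    genes = annot["gene"].to_numpy()
    rows = []
    for ridx, row in regions.iterrows():
        span_genes = pd.unique(genes[int(row["start_idx"]):int(row["end_idx"]) + 1])
        span_genes = [g for g in span_genes if g]
        if not span_genes:
            span_genes = [""]
        for g in span_genes:
            rec = row.to_dict()
            rec["region_id"] = ridx
            rec["gene"] = g
            rows.append(rec)
    cols = list(regions.columns) + ["region_id", "gene"]
    return pd.DataFrame(rows, columns=cols)


def case_exclusive_genes(
    annotated: pd.DataFrame, sheet: pd.DataFrame
) -> pd.DataFrame:
    """Genes whose epivariations occur in at least one case and no control.

    Returns a frame indexed by gene with case carrier counts and a
    hyper/hypo/mixed region tally. Requires regions to have been computed
    for cases **and** controls — exclusivity is meaningless otherwise.
    """
    annotated = annotated[annotated["gene"].astype(bool)]
    if annotated.empty:
        return pd.DataFrame(
            columns=["n_case_carriers", "n_hyper", "n_hypo", "n_mixed"]
        )
    pheno = sheet["phenotype"]
    is_case = annotated["subject_id"].map(pheno).eq("case")
    rows = []
    for gene, grp in annotated.groupby("gene", sort=True):
        case_mask = is_case.loc[grp.index]
        if case_mask.all() and case_mask.any():
            cases = grp.loc[case_mask]
            rows.append(
                {
                    "gene": gene,
                    "n_case_carriers": cases["subject_id"].nunique(),
                    "n_hyper": int((cases["direction"] == "hyper").sum()),
                    "n_hypo": int((cases["direction"] == "hypo").sum()),
                    "n_mixed": int((cases["direction"] == "mixed").sum()),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["n_case_carriers", "n_hyper", "n_hypo", "n_mixed"]
        )
    return pd.DataFrame(rows).set_index("gene")
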