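"""Synthetic methylation cohorts with ground truth.

Generates probe x subject beta matrices with the statistical structure the
downstream analysis assumes — bimodal beta-value distributions, covariates
(sex, age, blood cell fractions), and optional injected signal:

* **stochastic epigenetic mutations (SEMs)** — isolated per-cell outliers
  placed strictly beyond the control-derived 3xIQR fence for their probe;
* **epivariations** — contiguous probe runs shifted in specific carriers;
* **differentially methylated positions (DMPs)** — probe-level mean shifts
  in all cases.

Every injection is recorded in a truth table so recovery can be scored
exactly. All randomness flows through a single integer seed; identical
configurations and seeds reproduce outputs bit for bit.

The default cohort mirrors a blood-methylation case/control study of 61
cases and 61 controls with slightly older cases and a group-shifted NK-cell
fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CELL_TYPES, FLAG_COLUMNS
from .sem import control_bounds

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "TruthTables",
    "generate_cohort",
    "inject_sems",
    "inject_epivariation",
    "inject_dmps",
]

#: clip bound keeping betas in the open interval (0, 1)
_EPS = 1e-4


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``beta_mixture`` is (low-mode mean, high-mode mean, fraction of probes in
    the low mode, Beta concentration); concentration 100 gives a per-probe
    SD of roughly 0.03, matching the tight unimodal clouds of a methylation
    array after normalisation. Ages are Normal per group; cell fractions
    are Dirichlet with per-group concentration vectors so that a group-
    associated cell type (here NK) can be emulated.
    """

    n_cases: int = 61
    n_controls: int = 61
    n_chromosomes: int = 4
    probes_per_chromosome: int = 5000
    probes_per_gene: int = 10
    bp_spacing: int = 1000
    beta_mixture: tuple[float, float, float, float] = (0.10, 0.85, 0.60, 100.0)
    age_params: tuple[float, float, float] = (50.6, 48.0, 10.0)
    sex_imbalance: float = 0.6  # fraction male in each group
    cell_fractions: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            # Dirichlet concentrations per cell type (CD4T, CD8T, B, NK, Mono, Gran)
            "control": (30.0, 20.0, 10.0, 14.0, 16.0, 110.0),
            "case": (30.0, 20.0, 10.0, 8.0, 16.0, 116.0),
        }
    )
    flag_rates: dict[str, float] = field(
        default_factory=lambda: {
            "high_detection_p": 0.010,
            "low_beadcount": 0.002,
            "not_cpg_start": 0.008,
            "masked_list": 0.010,
            "sex_chromosome": 0.0,
        }
    )
    n_batches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_chromosomes",
                     "probes_per_chromosome", "probes_per_gene", "bp_spacing"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        low, high, frac, conc = self.beta_mixture
        if not (0.0 < low < 1.0 and 0.0 < high < 1.0):
            raise ConfigError("beta mixture mode means must lie in (0, 1)")
        if not 0.0 <= frac <= 1.0:
            raise ConfigError("low-mode fraction must lie in [0, 1]")
        if conc <= 0:
            raise ConfigError("beta mixture concentration must be positive")
        if not 0.0 <= self.sex_imbalance <= 1.0:
            raise ConfigError("sex_imbalance must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.n_chromosomes * self.probes_per_chromosome

    @property
    def n_subjects(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class TruthTables:
    """Ground truth of injected signal.

    ``sem`` has columns probe_id, subject_id, direction; ``regions`` has
    subject_id, chrom, start_idx, end_idx (inclusive probe indices into the
    annotation order), direction and genes; ``dmps`` has probe_id, delta.
    ``skipped_sems`` logs injections abandoned because no value could
    violate the probe's fence.
    """

    sem: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["probe_id", "subject_id", "direction"]))
    regions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["subject_id", "chrom", "start_idx", "end_idx", "direction", "genes"]))
    dmps: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["probe_id", "delta"]))
    skipped_sems: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["probe_id", "subject_id", "reason"]))


def _subject_ids(config: CohortConfig) -> tuple[list[str], list[str]]:
    cases = [f"case_{i + 1:03d}" for i in range(config.n_cases)]
    controls = [f"ctrl_{i + 1:03d}" for i in range(config.n_controls)]
    return cases, controls


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a clean (signal-free) cohort from *config*.

    Per probe, a mode (low/high methylation) is assigned once and a probe
    mean is jittered around the mode mean; per subject, betas are drawn
    from Beta(m*c, (1-m)*c) around the probe mean m. Case and control
    distributions are exchangeable — all group signal is injected later.

    Returns ``(beta, sheet, annotation)``.
    """
    rng = np.random.default_rng(config.seed)
    n_probes, n_sub = config.n_probes, config.n_subjects
    low, high, low_frac, conc = config.beta_mixture

    probe_ids = np.array([f"cg{i:08d}" for i in range(n_probes)])
    chroms = np.repeat(
        [f"chr{c + 1}" for c in range(config.n_chromosomes)],
        config.probes_per_chromosome,
    )
    pos = np.tile(
        1 + config.bp_spacing * np.arange(config.probes_per_chromosome),
        config.n_chromosomes,
    )
    gene_idx = np.arange(n_probes) // config.probes_per_gene
    genes = np.array([f"GENE{g:05d}" for g in gene_idx])

    is_low = rng.random(n_probes) < low_frac
    mode_mean = np.where(is_low, low, high)
    # probe-level jitter around the mode keeps probes distinct without
    # breaking bimodality (concentration 300 => SD ~ 0.02)
    probe_mean = rng.beta(mode_mean * 300.0, (1.0 - mode_mean) * 300.0)
    a = probe_mean * conc
    b = (1.0 - probe_mean) * conc
    values = rng.beta(a[:, None], b[:, None], size=(n_probes, n_sub))
    values = np.clip(values, _EPS, 1.0 - _EPS)

    case_ids, control_ids = _subject_ids(config)
    subject_ids = case_ids + control_ids
    beta = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                        columns=subject_ids)

    mean_case, mean_control, sd = config.age_params
    phenotype = ["case"] * config.n_cases + ["control"] * config.n_controls
    age = np.concatenate([
        rng.normal(mean_case, sd, config.n_cases),
        rng.normal(mean_control, sd, config.n_controls),
    ]).round(1)
    sex = np.where(rng.random(n_sub) < config.sex_imbalance, "M", "F")
    batch = np.array([f"b{rng.integers(1, config.n_batches + 1)}" for _ in range(n_sub)])
    cells = np.vstack([
        rng.dirichlet(config.cell_fractions["case"], config.n_cases),
        rng.dirichlet(config.cell_fractions["control"], config.n_controls),
    ])
    sheet = pd.DataFrame(
        {"phenotype": phenotype, "sex": sex, "age": age, "batch": batch},
        index=pd.Index(subject_ids, name="subject_id"),
    )
    for j, cell in enumerate(CELL_TYPES):
        sheet[cell] = cells[:, j]

    annot = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "gene": genes},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    for flag in FLAG_COLUMNS:
        rate = config.flag_rates.get(flag, 0.0)
        annot[flag] = rng.random(n_probes) < rate
    return beta, sheet, annot


def inject_sems(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    rate_controls: float,
    rate_cases: float,
    seed: int,
) -> tuple[pd.DataFrame, TruthTables]:
    """Scatter outlier SEMs into the matrix at per-cell Bernoulli rates.

    Fences are the 3xIQR bounds computed from the *pre-injection* control
    betas, so every injected value is a true outlier by construction: it is
    pushed at least 0.05 beyond the fence (towards whichever extreme has
    more headroom) and stays inside (0, 1). Cells whose fence already covers
    the whole unit interval are logged in ``skipped_sems`` instead of being
    silently dropped.
    """
    if not (0.0 <= rate_controls < 1.0 and 0.0 <= rate_cases < 1.0):
        raise ValueError("injection rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    truth = TruthTables()
    if rate_controls == 0.0 and rate_cases == 0.0:
        return beta.copy(), truth

    bounds = control_bounds(beta, sheet, min_controls=2).bounds
    lower = bounds["lower"].reindex(beta.index).to_numpy()
    upper = bounds["upper"].reindex(beta.index).to_numpy()

    is_case = (sheet.loc[beta.columns, "phenotype"] == "case").to_numpy()
    rates = np.where(is_case, rate_cases, rate_controls)
    hit = rng.random(beta.shape) < rates[None, :]
    out = beta.to_numpy().copy()

    margin = 0.05
    probe_pos, subj_pos = np.nonzero(hit)
    records, skipped = [], []
    for i, j in zip(probe_pos, subj_pos):
        room_hyper = (1.0 - _EPS) - (upper[i] + margin)
        room_hypo = (lower[i] - margin) - _EPS
        if room_hyper <= 0 and room_hypo <= 0:
            skipped.append((beta.index[i], beta.columns[j], "fence covers (0,1)"))
            continue
        # push towards whichever extreme leaves more headroom
        if room_hyper >= room_hypo:
            value = upper[i] + margin + rng.random() * room_hyper
            direction = "hyper"
        else:
            value = lower[i] - margin - rng.random() * room_hypo
            direction = "hypo"
        out[i, j] = value
        records.append((beta.index[i], beta.columns[j], direction))

    truth.sem = pd.DataFrame(records, columns=["probe_id", "subject_id", "direction"])
    truth.skipped_sems = pd.DataFrame(skipped, columns=["probe_id", "subject_id", "reason"])
    if skipped:
        logger.warning("inject_sems: %d injections skipped (fence spans unit interval)",
                       len(skipped))
    return pd.DataFrame(out, index=beta.index, columns=beta.columns), truth


def inject_epivariation(
    beta: pd.DataFrame,
    annot: pd.DataFrame,
    n_regions: int,
    region_width: int,
    carriers: list[str],
    direction: str,
    shift: float,
    seed: int,
    *,
    align_to_genes: bool = False,
    avoid_clipping: bool = False,
) -> tuple[pd.DataFrame, TruthTables]:
    """Shift contiguous probe runs in the given carriers.

    Regions are non-overlapping runs of ``region_width`` consecutive probes
    within a single chromosome; every carrier's betas over the run are moved
    by ``+shift`` (hyper) or ``-shift`` (hypo) and clipped to (0, 1). With
    ``align_to_genes`` the run start coincides with a gene start, so a
    region of gene width covers exactly one gene. With ``avoid_clipping``
    only runs where no carrier value saturates at the unit-interval boundary
    are eligible — a hypermethylation shift at an already-saturated locus is
    not representable on the beta scale (mirroring real arrays, where fully
    methylated CpGs cannot show hyper-outliers).
    """
    if region_width < 2:
        raise ValueError("region_width must be >= 2")
    if not 0.0 <= shift < 1.0:
        raise ValueError("shift must lie in [0, 1)")
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    missing = set(carriers) - set(beta.columns)
    if missing:
        raise ValueError(f"carriers not in cohort: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    annot = annot.loc[beta.index]
    chrom_arr = annot["chrom"].to_numpy()
    gene_arr = annot["gene"].to_numpy()

    # candidate run starts: region fully inside one chromosome
    starts = []
    offset = 0
    for chrom, grp in annot.groupby("chrom", sort=False):
        n = len(grp)
        starts.extend(range(offset, offset + n - region_width + 1))
        offset += n
    if align_to_genes:
        starts = [s for s in starts if s == 0 or gene_arr[s] != gene_arr[s - 1]]
    if avoid_clipping and shift > 0:
        values = beta.to_numpy()
        col_sel = [beta.columns.get_loc(c) for c in carriers]
        ok = []
        for s in starts:
            block = values[s:s + region_width][:, col_sel]
            if direction == "hyper":
                feasible = (block + shift <= 1.0 - 2 * _EPS).all()
            else:
                feasible = (block - shift >= 2 * _EPS).all()
            if feasible:
                ok.append(s)
        starts = ok

    rng.shuffle(starts)
    chosen: list[int] = []
    for s in starts:
        if all(abs(s - c) >= region_width for c in chosen):
            chosen.append(s)
        if len(chosen) == n_regions:
            break
    if len(chosen) < n_regions:
        raise ValueError(
            f"cannot place {n_regions} non-overlapping regions of width "
            f"{region_width}: only {len(chosen)} fit"
        )
    chosen.sort()

    out = beta.to_numpy().copy()
    col_idx = [beta.columns.get_loc(c) for c in carriers]
    delta = shift if direction == "hyper" else -shift
    records = []
    for s in chosen:
        e = s + region_width - 1
        if shift > 0:
            block = out[s:e + 1][:, col_idx]
            out[s:e + 1, col_idx] = np.clip(block + delta, _EPS, 1.0 - _EPS)
        genes = ",".join(pd.unique(gene_arr[s:e + 1]))
        for carrier in carriers:
            records.append((carrier, chrom_arr[s], s, e, direction, genes))
    truth = TruthTables()
    truth.regions = pd.DataFrame(
        records,
        columns=["subject_id", "chrom", "start_idx", "end_idx", "direction", "genes"],
    )
    return pd.DataFrame(out, index=beta.index, columns=beta.columns), truth


def inject_dmps(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    n_probes: int,
    delta: float,
    seed: int,
) -> tuple[pd.DataFrame, TruthTables]:
    """Shift ``n_probes`` random probes by ``delta`` in every case.

    Emulates case/control differentially methylated positions: the case
    mean at each selected probe moves by ``delta`` (clipped to (0, 1)),
    controls are untouched.
    """
    if abs(delta) >= 1.0:
        raise ValueError("|delta| must be < 1")
    if n_probes > beta.shape[0]:
        raise ValueError(
            f"n_probes={n_probes} exceeds available probes ({beta.shape[0]})"
        )
    rng = np.random.default_rng(seed)
    truth = TruthTables()
    if n_probes == 0 or delta == 0.0:
        truth.dmps = pd.DataFrame(columns=["probe_id", "delta"])
        return beta.copy(), truth

    probes = rng.choice(beta.shape[0], size=n_probes, replace=False)
    probes.sort()
    case_cols = np.nonzero((sheet.loc[beta.columns, "phenotype"] == "case").to_numpy())[0]
    out = beta.to_numpy().copy()
    block = out[np.ix_(probes, case_cols)]
    out[np.ix_(probes, case_cols)] = np.clip(block + delta, _EPS, 1.0 - _EPS)
    truth.dmps = pd.DataFrame(
        {"probe_id": beta.index[probes], "delta": delta}
    )
    return pd.DataFrame(out, index=beta.index, columns=beta.columns), truth
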