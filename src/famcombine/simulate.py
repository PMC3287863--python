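"""Synthetic mini-exome replicates: genotypes, trios and liability phenotypes.

The generator emulates the statistical structure of a sequenced mini-exome
cohort: a rare-skewed minor-allele-frequency spectrum, Hardy-Weinberg
founders, Mendelian trio transmission, and a binary disease defined by
thresholding an additive liability

    l_i = sum_j beta_j g_ij + eps_i,   eps_i ~ Normal(0, noise_sd^2),

with the threshold calibrated so the marginal prevalence hits a target
(default 30%, a common disease).  The default design matches the mixed study
it is built to exercise: 697 unrelated subjects and 194 complete trios, with
replicates that keep one fixed genotype matrix and redraw phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import stats

from .core import (
    CombinedSample,
    GenotypeMatrix,
    Individual,
    Role,
    SNPInfo,
    Trio,
    classify_maf,
)

# rare_skewed spectrum: stratum weights and log-uniform MAF ranges
_RARE_SKEWED_STRATA = (
    (0.55, 5e-4, 0.01),
    (0.225, 0.01, 0.05),
    (0.225, 0.05, 0.5),
)


@dataclass
class Stratification:
    """Optional two-or-more subpopulation structure (Balding-Nichols style).

    ``fst`` controls allele-frequency divergence; ``risk_shift`` adds a
    per-subpopulation constant to the liability, which confounds naive
    case-control comparisons and is how stratification robustness is probed.
    """

    n_subpops: int = 2
    fst: float = 0.05
    proportions: tuple[float, ...] | None = None
    risk_shift: tuple[float, ...] | None = None


@dataclass
class LiabilityModel:
    """Additive liability-threshold phenotype model."""

    mafs: np.ndarray
    betas: np.ndarray
    noise_sd: float = 1.0
    threshold: float | None = None
    target_prevalence: float = 0.30

    def __post_init__(self) -> None:
        self.mafs = np.asarray(self.mafs, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        if self.mafs.shape != self.betas.shape:
            raise ValueError("mafs and betas must have equal length")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0, 1)")

    @property
    def causal_idx(self) -> np.ndarray:
        return np.nonzero(self.betas != 0.0)[0]


@dataclass
class PopulationConfig:
    n_snps: int = 2000
    maf_spectrum: str = "rare_skewed"  # rare_skewed | uniform | fixed_list
    spectrum_params: dict = field(default_factory=dict)
    n_unrelated: int = 697
    n_trios: int = 194
    trio_ascertainment: str = "random"  # random | offspring_affected | mixed
    case_trio_fraction: float = 0.5  # for mixed ascertainment
    unrelated_case_fraction: float | None = None  # None = population cohort
    stratification: Stratification | None = None

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_unrelated < 0 or self.n_trios < 0:
            raise ValueError("counts must be positive")


def draw_mafs(config: PopulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-SNP minor allele frequencies under the configured spectrum."""
    n = config.n_snps
    if config.maf_spectrum == "fixed_list":
        mafs = np.asarray(config.spectrum_params["mafs"], dtype=float)
        if mafs.size != n:
            raise ValueError("fixed_list length must equal n_snps")
    elif config.maf_spectrum == "uniform":
        lo = config.spectrum_params.get("low", 0.01)
        hi = config.spectrum_params.get("high", 0.5)
        mafs = rng.uniform(lo, hi, size=n)
    elif config.maf_spectrum == "rare_skewed":
        weights = np.array([w for w, _, _ in _RARE_SKEWED_STRATA])
        stratum = rng.choice(len(_RARE_SKEWED_STRATA), size=n, p=weights)
        u = rng.uniform(size=n)
        mafs = np.empty(n)
        for k, (_, lo, hi) in enumerate(_RARE_SKEWED_STRATA):
            sel = stratum == k
            mafs[sel] = np.exp(np.log(lo) + u[sel] * (np.log(hi) - np.log(lo)))
    else:
        raise ValueError(f"unknown maf_spectrum {config.maf_spectrum!r}")
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("MAFs must lie in (0, 0.5]")
    return mafs


def _subpop_freqs(
    mafs: np.ndarray, strat: Stratification, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies, (n_subpops x n_snps)."""
    f = strat.fst
    a = mafs * (1 - f) / f
    b = (1 - mafs) * (1 - f) / f
    return rng.beta(a, b, size=(strat.n_subpops, mafs.size))


def simulate_unrelated(
    n: int, mafs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """HWE genotypes: entries Binomial(2, maf), independent across SNPs."""
    mafs = np.asarray(mafs, dtype=float)
    return rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.int16)


def simulate_trio_genotypes(
    n_trios: int, mafs: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """HWE parents; each transmits one of its two alleles uniformly at random."""
    father = simulate_unrelated(n_trios, mafs, rng)
    mother = simulate_unrelated(n_trios, mafs, rng)
    # a parent with genotype g transmits the minor allele with probability g/2
    t_f = rng.random(father.shape) < father / 2.0
    t_m = rng.random(mother.shape) < mother / 2.0
    offspring = (t_f.astype(np.int16) + t_m.astype(np.int16))
    return father, mother, offspring


def liability(
    genotypes: np.ndarray, model: LiabilityModel, rng: np.random.Generator,
    shift: np.ndarray | float = 0.0,
) -> np.ndarray:
    ci = model.causal_idx
    genetic = genotypes[:, ci] @ model.betas[ci] if ci.size else 0.0
    eps = rng.normal(0.0, model.noise_sd, size=genotypes.shape[0])
    return genetic + eps + shift


def assign_phenotypes(
    genotypes: np.ndarray, model: LiabilityModel, rng: np.random.Generator,
    shift: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Binary affection: 1 where the liability exceeds the model threshold."""
    if model.threshold is None:
        raise ValueError("threshold not set; call calibrate_threshold first")
    return (liability(genotypes, model, rng, shift) > model.threshold).astype(int)


def calibrate_threshold(
    model: LiabilityModel,
    n_probe: int = 100_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Affection cutoff as the (1 - K) quantile of liability in a probe cohort.

    Only causal SNPs enter the liability, so the probe draws genotypes at
    those sites alone.  With no causal SNPs the closed form
    ``noise_sd * Phi^-1(1 - K)`` is returned.
    """
    K = model.target_prevalence
    ci = model.causal_idx
    if ci.size == 0:
        return float(model.noise_sd * stats.norm.ppf(1 - K))
    rng = rng or np.random.default_rng()
    g = simulate_unrelated(n_probe, model.mafs[ci], rng)
    liab = g @ model.betas[ci] + rng.normal(0.0, model.noise_sd, size=n_probe)
    if np.ptp(liab) == 0:
        raise ValueError("degenerate liability distribution")
    return float(np.quantile(liab, 1 - K))


def default_liability_model(
    mafs: np.ndarray,
    causal_fraction: float = 0.01,
    beta_range: tuple[float, float] = (0.2, 1.2),
    target_prevalence: float = 0.32,
    rng: np.random.Generator | None = None,
) -> LiabilityModel:
    """Liability model with a small fraction of causal SNPs whose effects are
    uniform on ``beta_range`` (mirroring the spread seen in exome-style
    simulated architectures).

    The default target prevalence of 32% models a common disease whose
    prevalence clearly exceeds 30%; 30% itself is treated as a lower bound,
    not a point target.
    """
    rng = rng or np.random.default_rng()
    n = len(mafs)
    betas = np.zeros(n)
    n_causal = max(1, int(round(causal_fraction * n))) if causal_fraction > 0 else 0
    if n_causal:
        idx = rng.choice(n, size=n_causal, replace=False)
        betas[idx] = rng.uniform(*beta_range, size=n_causal)
    model = LiabilityModel(mafs=mafs, betas=betas, target_prevalence=target_prevalence)
    model.threshold = calibrate_threshold(model, rng=rng)
    return model


def default_model_prevalence(
    n_cohort: int = 100_000, seed: int = 0,
    config: PopulationConfig | None = None,
) -> float:
    """Empirical affected fraction in a large unrelated cohort under the
    default liability model (default population, calibrated threshold).

    Only causal SNPs enter the liability, so the cohort is drawn at those
    sites alone; the affected fraction is distributed identically to one
    computed from the full genotype matrix.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    config = config or PopulationConfig()
    mafs = draw_mafs(config, rng)
    model = default_liability_model(mafs, rng=rng)
    ci = model.causal_idx
    g = simulate_unrelated(n_cohort, model.mafs[ci], rng)
    liab = g @ model.betas[ci] + rng.normal(0.0, model.noise_sd, size=n_cohort)
    return float((liab > model.threshold).mean())


def _make_sample(
    unrel_g: np.ndarray,
    unrel_y: np.ndarray,
    trio_g: tuple[np.ndarray, np.ndarray, np.ndarray],
    trio_y: tuple[np.ndarray, np.ndarray, np.ndarray],
    snp_ids: list[str],
) -> CombinedSample:
    f_g, m_g, o_g = trio_g
    f_y, m_y, o_y = trio_y
    n_u, n_t = unrel_g.shape[0], f_g.shape[0]

    rows = [unrel_g] + ([np.vstack([f_g, m_g, o_g])] if n_t else [])
    values = np.vstack(rows) if rows else unrel_g
    ids = [f"U{i+1}" for i in range(n_u)]
    ids += [f"T{i+1}_F" for i in range(n_t)]
    ids += [f"T{i+1}_M" for i in range(n_t)]
    ids += [f"T{i+1}_O" for i in range(n_t)]
    gmat = GenotypeMatrix(values, snp_ids=snp_ids, individual_ids=ids)

    individuals: dict[str, Individual] = {}
    for i in range(n_u):
        individuals[f"U{i+1}"] = Individual(
            iid=f"U{i+1}", affected=int(unrel_y[i]), role=Role.UNRELATED
        )
    trios = []
    for i in range(n_t):
        fa = Individual(iid=f"T{i+1}_F", affected=int(f_y[i]), role=Role.PARENT)
        mo = Individual(iid=f"T{i+1}_M", affected=int(m_y[i]), role=Role.PARENT)
        of = Individual(
            iid=f"T{i+1}_O", father_id=fa.iid, mother_id=mo.iid,
            affected=int(o_y[i]), role=Role.OFFSPRING,
        )
        individuals[fa.iid] = fa
        individuals[mo.iid] = mo
        individuals[of.iid] = of
        trios.append(
            Trio(
                father=fa, mother=mo, offspring=of,
                father_idx=gmat.row_index(fa.iid),
                mother_idx=gmat.row_index(mo.iid),
                offspring_idx=gmat.row_index(of.iid),
            )
        )
    return CombinedSample(
        genotypes=gmat,
        individuals=individuals,
        unrelated_idx=np.arange(n_u),
        trios=trios,
    )


def _draw_genotypes(
    config: PopulationConfig, mafs: np.ndarray, rng: np.random.Generator
):
    """All genotype material for one design, plus per-individual liability shifts."""
    strat = config.stratification
    if strat is None:
        unrel = simulate_unrelated(config.n_unrelated, mafs, rng)
        trio = simulate_trio_genotypes(config.n_trios, mafs, rng)
        return unrel, trio, 0.0, 0.0

    props = np.asarray(strat.proportions or [1 / strat.n_subpops] * strat.n_subpops)
    freqs = _subpop_freqs(mafs, strat, rng)
    shifts = np.asarray(strat.risk_shift or np.zeros(strat.n_subpops))

    pop_u = rng.choice(strat.n_subpops, size=config.n_unrelated, p=props)
    unrel = np.empty((config.n_unrelated, mafs.size), dtype=np.int16)
    for k in range(strat.n_subpops):
        sel = pop_u == k
        unrel[sel] = simulate_unrelated(int(sel.sum()), freqs[k], rng)

    pop_t = rng.choice(strat.n_subpops, size=config.n_trios, p=props)
    f = np.empty((config.n_trios, mafs.size), dtype=np.int16)
    m = np.empty_like(f)
    o = np.empty_like(f)
    for k in range(strat.n_subpops):
        sel = pop_t == k
        fk, mk, ok = simulate_trio_genotypes(int(sel.sum()), freqs[k], rng)
        f[sel], m[sel], o[sel] = fk, mk, ok
    return unrel, (f, m, o), shifts[pop_u], shifts[pop_t]


def generate_replicate(
    config: PopulationConfig,
    model: LiabilityModel,
    rng: np.random.Generator,
    mafs: np.ndarray | None = None,
    retry_budget: int = 50,
) -> tuple[CombinedSample, list[SNPInfo]]:
    """One full study sample: unrelateds + trios with phenotypes and truth table.

    Ascertainment: ``random`` keeps trios as drawn; ``offspring_affected``
    resamples until every kept trio has an affected offspring; ``mixed`` hits a
    configured case:control trio split.  Unrelateds are a population cohort
    unless ``unrelated_case_fraction`` demands a case/control quota.
    """
    mafs = draw_mafs(config, rng) if mafs is None else np.asarray(mafs, dtype=float)
    if model.mafs.size != mafs.size:
        raise ValueError("liability model and population disagree on SNP count")
    if model.threshold is None:
        model = replace(model, threshold=calibrate_threshold(model, rng=rng))

    unrel_g, trio_g, shift_u, shift_t = _draw_genotypes(config, mafs, rng)
    f_g, m_g, o_g = trio_g

    unrel_g, unrel_y = _sample_unrelated(
        unrel_g, shift_u, config, model, rng, mafs, retry_budget
    )
    o_y = assign_phenotypes(o_g, model, rng, shift_t) if config.n_trios else np.empty(0, int)
    f_g, m_g, o_g, o_y = _ascertain_trios(
        config, model, rng, mafs, (f_g, m_g, o_g), o_y, shift_t, retry_budget
    )
    f_y = assign_phenotypes(f_g, model, rng) if config.n_trios else np.empty(0, int)
    m_y = assign_phenotypes(m_g, model, rng) if config.n_trios else np.empty(0, int)

    snp_ids = [f"S{j+1}" for j in range(mafs.size)]
    sample = _make_sample(unrel_g, unrel_y, (f_g, m_g, o_g), (f_y, m_y, o_y), snp_ids)
    truth = [
        SNPInfo(
            snp_id=snp_ids[j], maf=float(mafs[j]),
            causal=bool(model.betas[j] != 0), beta=float(model.betas[j]),
            maf_class=classify_maf(float(mafs[j])),
        )
        for j in range(mafs.size)
    ]
    return sample, truth


def _sample_unrelated(
    unrel_g, shift_u, config, model, rng, mafs, retry_budget
) -> tuple[np.ndarray, np.ndarray]:
    """Phenotypes for unrelateds; with a case-fraction quota, whole subjects
    (genotype + phenotype) are resampled until the quota is met."""
    if config.n_unrelated == 0:
        return unrel_g, np.empty(0, int)
    y = assign_phenotypes(unrel_g, model, rng, shift_u)
    frac = config.unrelated_case_fraction
    if frac is None:
        return unrel_g, y
    if config.stratification is not None:
        raise ValueError("case-fraction quota not supported with stratification")
    want_cases = int(round(frac * config.n_unrelated))
    want_controls = config.n_unrelated - want_cases
    kept_g, kept_y = [], []
    n_cases = n_controls = 0
    g_cur, y_cur = unrel_g, y
    for attempt in range(retry_budget + 1):
        for i in range(len(y_cur)):
            if y_cur[i] == 1 and n_cases < want_cases:
                n_cases += 1
            elif y_cur[i] == 0 and n_controls < want_controls:
                n_controls += 1
            else:
                continue
            kept_g.append(g_cur[i])
            kept_y.append(y_cur[i])
        if n_cases == want_cases and n_controls == want_controls:
            break
        if attempt == retry_budget:
            raise RuntimeError("unrelated case/control quota not met within budget")
        g_cur = simulate_unrelated(config.n_unrelated, mafs, rng)
        y_cur = assign_phenotypes(g_cur, model, rng)
    return np.asarray(kept_g, dtype=np.int16), np.asarray(kept_y, dtype=int)


def _ascertain_trios(config, model, rng, mafs, trio_g, o_y, shift_t, retry_budget):
    f_g, m_g, o_g = trio_g
    mode = config.trio_ascertainment
    if mode == "random" or config.n_trios == 0:
        return f_g, m_g, o_g, o_y
    if config.stratification is not None:
        raise ValueError("phenotype-based trio ascertainment not supported with stratification")
    if mode == "offspring_affected":
        want_cases, want_controls = config.n_trios, 0
    elif mode == "mixed":
        want_cases = int(round(config.case_trio_fraction * config.n_trios))
        want_controls = config.n_trios - want_cases
    else:
        raise ValueError(f"unknown trio_ascertainment {mode!r}")

    kept_f, kept_m, kept_o, kept_y = [], [], [], []
    n_cases = n_controls = 0
    cur = (f_g, m_g, o_g, o_y)
    for attempt in range(retry_budget + 1):
        f, m, o, y = cur
        for i in range(len(y)):
            if y[i] == 1 and n_cases < want_cases:
                n_cases += 1
            elif y[i] == 0 and n_controls < want_controls:
                n_controls += 1
            else:
                continue
            kept_f.append(f[i])
            kept_m.append(m[i])
            kept_o.append(o[i])
            kept_y.append(y[i])
        if n_cases == want_cases and n_controls == want_controls:
            break
        if attempt == retry_budget:
            raise RuntimeError(
                f"trio ascertainment failed: have {n_cases}+{n_controls} of "
                f"{want_cases}+{want_controls} after {retry_budget} batches"
            )
        f, m, o = simulate_trio_genotypes(config.n_trios, mafs, rng)
        y = assign_phenotypes(o, model, rng)
        cur = (f, m, o, y)
    return (
        np.asarray(kept_f, dtype=np.int16),
        np.asarray(kept_m, dtype=np.int16),
        np.asarray(kept_o, dtype=np.int16),
        np.asarray(kept_y, dtype=int),
    )


def replicate_stream(
    config: PopulationConfig,
    model: LiabilityModel | None,
    n_replicates: int,
    seed: int,
    fixed_genotypes: bool = True,
    model_kwargs: dict | None = None,
    mafs: np.ndarray | None = None,
) -> Iterator[tuple[int, CombinedSample, list[SNPInfo]]]:
    """Yield ``(replicate_index, sample, truth)`` reproducibly.

    ``fixed_genotypes=True`` mimics a shared-genotype replicate design: one genotype
    matrix is drawn once and only the phenotype noise is redrawn per
    replicate.  Each replicate uses a deterministic child stream of the master
    seed, so any single replicate is reproducible in isolation.
    """
    ss = np.random.SeedSequence(seed)
    base_rng = np.random.default_rng(ss.spawn(1)[0])
    mafs = draw_mafs(config, base_rng) if mafs is None else np.asarray(mafs, dtype=float)
    if model is None:
        model = default_liability_model(mafs, rng=base_rng, **(model_kwargs or {}))
    if model.threshold is None:
        model = replace(model, threshold=calibrate_threshold(model, rng=base_rng))

    fixed = None
    if fixed_genotypes:
        if config.trio_ascertainment != "random":
            raise ValueError(
                "fixed-genotype replicates require random trio ascertainment "
                "(offspring affection is redrawn each replicate)"
            )
        fixed = _draw_genotypes(config, mafs, base_rng)

    children = ss.spawn(n_replicates + 1)[1:]
    for r in range(n_replicates):
        rng = np.random.default_rng(children[r])
        if fixed is not None:
            unrel_g, (f_g, m_g, o_g), shift_u, shift_t = fixed
            unrel_y = (
                assign_phenotypes(unrel_g, model, rng, shift_u)
                if config.n_unrelated else np.empty(0, int)
            )
            ys = [
                assign_phenotypes(g, model, rng, shift_t)
                if config.n_trios else np.empty(0, int)
                for g in (f_g, m_g, o_g)
            ]
            snp_ids = [f"S{j+1}" for j in range(mafs.size)]
            sample = _make_sample(unrel_g, unrel_y, (f_g, m_g, o_g), tuple(ys), snp_ids)
            truth = [
                SNPInfo(
                    snp_id=snp_ids[j], maf=float(mafs[j]),
                    causal=bool(model.betas[j] != 0), beta=float(model.betas[j]),
                    maf_class=classify_maf(float(mafs[j])),
                )
                for j in range(mafs.size)
            ]
        else:
            sample, truth = generate_replicate(config, model, rng, mafs=mafs)
        yield r, sample, truth
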