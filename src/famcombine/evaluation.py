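"""Simulation experiment: run every test on every SNP over replicates and
summarize empirical rejection rates.

The experiment design mirrors a mixed-cohort evaluation: one genotype matrix
held fixed across replicates, phenotypes redrawn each replicate from the
liability model, every SNP tested by each method at a nominal level (no
multiple-testing adjustment, so methods are compared on a common scale), and
rejection rates reported for noncausal SNPs (empirical type-I error), causal
SNPs (average power), per-SNP power by MAF class and effect size, and a
top-SNP comparison table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chen_lin, zhang, zhu
from .core import CombinedSample, SNPInfo, Status, results_to_frame
from .pca import fit_pcs
from .simulate import (
    LiabilityModel,
    PopulationConfig,
    calibrate_threshold,
    generate_replicate,
    replicate_stream,
)

logger = logging.getLogger(__name__)

METHODS = ("chen_lin", "zhu", "zhang")


@dataclass
class ExperimentConfig:
    n_replicates: int = 200
    alpha: float = 0.05
    methods: tuple[str, ...] = METHODS
    spurious_exclusion: tuple[str, ...] = ()
    seed: int = 0
    L: int = 10
    fixed_genotypes: bool = True
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def run_methods(
    sample: CombinedSample,
    methods: Sequence[str] = METHODS,
    L: int = 10,
) -> pd.DataFrame:
    """All requested per-SNP tests on one sample, as a tidy frame.

    The PC basis is fitted once and shared by the two PC-adjusted methods, so
    both see identical adjustment inputs.
    """
    basis = None
    if L > 0 and {"zhu", "zhang"} & set(methods):
        founders = sample.genotypes.values[
            sorted(set(sample.founder_idx().tolist()))
        ]
        basis = fit_pcs(founders, L)

    frames = []
    if "chen_lin" in methods:
        res = [
            chen_lin.chen_lin_test(sample, j)
            for j in range(sample.genotypes.n_snps)
        ]
        frames.append(results_to_frame(res))
    if "zhu" in methods:
        frames.append(results_to_frame(zhu.zhu_test_all(sample, L=L, basis=basis)))
    if "zhang" in methods:
        frames.append(results_to_frame(zhang.zhang_test_all(sample, L=L, basis=basis)))
    return pd.concat(frames, ignore_index=True)


def run_experiment(
    pop_config: PopulationConfig,
    model: LiabilityModel | None,
    exp_config: ExperimentConfig,
    mafs: np.ndarray | None = None,
) -> tuple[pd.DataFrame, list[SNPInfo]]:
    """Replicated experiment; returns the long results frame and the truth table.

    Reproducible under ``exp_config.seed``; a method failure on a SNP is
    recorded in its status and the run continues.
    """
    records = []
    truth: list[SNPInfo] = []
    ckpt = Path(exp_config.checkpoint_dir) if exp_config.checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)
    for r, sample, rep_truth in replicate_stream(
        pop_config, model, exp_config.n_replicates, exp_config.seed,
        fixed_genotypes=exp_config.fixed_genotypes, mafs=mafs,
    ):
        truth = rep_truth
        df = run_methods(sample, exp_config.methods, exp_config.L)
        df.insert(0, "replicate", r)
        n_bad = int((df["status"] != Status.OK.value).sum())
        logger.info("replicate %d: %d results, %d without a p-value", r, len(df), n_bad)
        if ckpt:
            df.to_csv(ckpt / f"replicate_{r:04d}.tsv", sep="\t", index=False,
                      na_rep="NA")
        records.append(df)
    return pd.concat(records, ignore_index=True), truth


@dataclass
class RejectionSummary:
    """Table-shaped rejection-rate summaries for one experiment."""

    by_method: pd.DataFrame          # noncausal (all / excl), causal rates
    per_snp: pd.DataFrame            # per (method, snp) power + truth
    by_stratum: pd.DataFrame         # (method, maf_class) mean power, causal SNPs
    alpha: float = 0.05
    degenerate_counts: dict = field(default_factory=dict)


def _rate(sub: pd.DataFrame, alpha: float) -> tuple[float, float]:
    """(rate counting missing p as non-rejection, rate among valid tests)."""
    tested = sub[sub["status"] != Status.MONOMORPHIC.value]
    if len(tested) == 0:
        return np.nan, np.nan
    rej = (tested["p_value"] <= alpha).fillna(False)
    valid = tested["p_value"].notna()
    rate_all = float(rej.mean())
    rate_valid = float(rej[valid].mean()) if valid.any() else np.nan
    return rate_all, rate_valid


def rejection_rates(
    results: pd.DataFrame,
    truth: Sequence[SNPInfo],
    alpha: float = 0.05,
    exclusions: Sequence[str] = (),
) -> RejectionSummary:
    """Empirical rejection rates stratified by causal status.

    Monomorphic SNPs are skipped (never tested); degenerate and
    no-informative-trio outcomes count as non-rejections in the headline
    rates (a ``*_valid`` column restricts to tests that produced a p-value).
    ``exclusions`` removes the named noncausal SNPs from the noncausal
    stratum, the spurious-gene-style sensitivity column.
    """
    info = {t.snp_id: t for t in truth}
    df = results.copy()
    df["causal"] = df["snp_id"].map(lambda s: info[s].causal)
    excl = set(exclusions)

    rows = []
    degen = {}
    for method, sub in df.groupby("method"):
        nc = sub[~sub["causal"]]
        nc_x = nc[~nc["snp_id"].isin(excl)]
        ca = sub[sub["causal"]]
        r_nc, rv_nc = _rate(nc, alpha)
        r_ncx, rv_ncx = _rate(nc_x, alpha)
        r_ca, rv_ca = _rate(ca, alpha)
        rows.append({
            "method": method,
            "rate_noncausal_all": r_nc,
            "rate_noncausal_excl_spurious": r_ncx,
            "rate_causal": r_ca,
            "rate_noncausal_all_valid": rv_nc,
            "rate_noncausal_excl_spurious_valid": rv_ncx,
            "rate_causal_valid": rv_ca,
        })
        degen[method] = int(
            (sub["status"].isin([Status.DEGENERATE.value,
                                 Status.NO_INFORMATIVE_TRIOS.value])).sum()
        )
    by_method = pd.DataFrame(rows).set_index("method")

    per_snp = (
        df.assign(reject=(df["p_value"] <= alpha).fillna(False),
                  tested=df["status"] != Status.MONOMORPHIC.value)
        .query("tested")
        .groupby(["method", "snp_id"], as_index=False)
        .agg(power=("reject", "mean"), n_replicates=("reject", "size"))
    )
    per_snp["maf"] = per_snp["snp_id"].map(lambda s: info[s].maf)
    per_snp["maf_class"] = per_snp["snp_id"].map(lambda s: info[s].maf_class)
    per_snp["beta"] = per_snp["snp_id"].map(lambda s: info[s].beta)
    per_snp["causal"] = per_snp["snp_id"].map(lambda s: info[s].causal)

    by_stratum = (
        per_snp[per_snp["causal"]]
        .groupby(["method", "maf_class"], as_index=False)
        .agg(mean_power=("power", "mean"), n_snps=("snp_id", "nunique"))
    )
    return RejectionSummary(
        by_method=by_method, per_snp=per_snp, by_stratum=by_stratum,
        alpha=alpha, degenerate_counts=degen,
    )


def power_by_strata(
    results: pd.DataFrame,
    truth: Sequence[SNPInfo],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-causal-SNP power against effect size, by MAF class (figure-shaped):
    one row per (method, snp) with its beta, MAF class and empirical power."""
    summary = rejection_rates(results, truth, alpha)
    tab = summary.per_snp[summary.per_snp["causal"]].copy()
    return tab.sort_values(["method", "maf_class", "beta"]).reset_index(drop=True)


def top_snp_table(
    results: pd.DataFrame,
    truth: Sequence[SNPInfo],
    alpha: float = 0.05,
    min_power: float = 0.2,
) -> pd.DataFrame:
    """Causal SNPs for which any method reaches ``min_power``, one column per
    method, with the best method(s) flagged (ties all flagged)."""
    summary = rejection_rates(results, truth, alpha)
    causal = summary.per_snp[summary.per_snp["causal"]]
    if causal.empty:
        return pd.DataFrame(columns=["snp_id", "beta", "maf", "best"])
    wide = causal.pivot_table(index="snp_id", columns="method",
                              values="power", fill_value=0.0)
    keep = wide.max(axis=1) >= min_power
    wide = wide[keep]
    info = {t.snp_id: t for t in truth}
    out = wide.reset_index()
    out["beta"] = out["snp_id"].map(lambda s: info[s].beta)
    out["maf"] = out["snp_id"].map(lambda s: info[s].maf)
    method_cols = [c for c in wide.columns]
    best = []
    for _, row in out.iterrows():
        top = max(row[c] for c in method_cols)
        winners = [c for c in method_cols if row[c] == top]
        best.append(",".join(sorted(winners)))
    out["best"] = best
    return out.sort_values("snp_id").reset_index(drop=True)


def null_calibration(
    n_snps: int = 2000,
    n_unrelated: int = 697,
    n_trios: int = 194,
    alpha: float = 0.05,
    seed: int = 0,
    min_tests_per_method: int = 2000,
    max_replicates: int = 10,
    L: int = 10,
    methods: tuple[str, ...] = METHODS,
) -> pd.DataFrame:
    """Null-design calibration: fixed genotypes, phenotypes redrawn with all
    liability effects zero, replicates accumulated until every method has at
    least ``min_tests_per_method`` valid tests.

    Returns one row per method: valid test count, rejections, and the
    empirical rejection rate among valid p-values.
    """
    pop = PopulationConfig(n_snps=n_snps, n_unrelated=n_unrelated,
                           n_trios=n_trios)
    counts = {m: 0 for m in methods}
    rejects = {m: 0 for m in methods}
    for r, sample, _truth in replicate_stream(
        pop, None, max_replicates, seed, fixed_genotypes=True,
        model_kwargs={"causal_fraction": 0.0, "target_prevalence": 0.30},
    ):
        df = run_methods(sample, methods, L)
        for m in methods:
            p = df.loc[df["method"] == m, "p_value"].dropna()
            counts[m] += len(p)
            rejects[m] += int((p <= alpha).sum())
        logger.info("null replicate %d: totals %s", r, counts)
        if all(counts[m] >= min_tests_per_method for m in methods):
            break
    rows = [
        {"method": m, "n_valid": counts[m], "n_rejected": rejects[m],
         "rate": rejects[m] / counts[m] if counts[m] else np.nan}
        for m in methods
    ]
    return pd.DataFrame(rows).set_index("method")


def power_grid(
    betas: Sequence[float] = (0.0, 0.2, 0.5, 1.0),
    maf: float = 0.05,
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    n_unrelated: int = 697,
    n_trios: int = 194,
    methods: tuple[str, ...] = METHODS,
) -> pd.DataFrame:
    """Single-SNP power across effect sizes at a fixed MAF.

    Each replicate simulates the full mixed design with one causal SNP and
    independent genotypes; PC adjustment is off (L = 0) since no structure is
    simulated and a one-SNP panel carries no ancestry information.  Rejection
    requires a valid p-value at or below ``alpha``.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    pop = PopulationConfig(n_snps=1, maf_spectrum="fixed_list",
                           spectrum_params={"mafs": [maf]},
                           n_unrelated=n_unrelated, n_trios=n_trios)
    for b_i, beta in enumerate(betas):
        model = LiabilityModel(mafs=np.array([maf]), betas=np.array([float(beta)]))
        model.threshold = calibrate_threshold(
            model, rng=np.random.default_rng(ss.spawn(1)[0])
        )
        children = np.random.SeedSequence((seed, b_i)).spawn(n_replicates)
        hits = {m: 0 for m in methods}
        for r in range(n_replicates):
            rng = np.random.default_rng(children[r])
            sample, _ = generate_replicate(pop, model, rng,
                                           mafs=np.array([maf]))
            if "chen_lin" in methods:
                res = chen_lin.chen_lin_test(sample, 0)
                hits["chen_lin"] += int(res.p_value is not None and res.p_value <= alpha)
            if "zhu" in methods:
                res = zhu.zhu_test(sample, 0, L=0)
                hits["zhu"] += int(res.p_value is not None and res.p_value <= alpha)
            if "zhang" in methods:
                res = zhang.zhang_test(sample, 0, L=0)
                hits["zhang"] += int(res.p_value is not None and res.p_value <= alpha)
        for m in methods:
            rows.append({"method": m, "beta": float(beta),
                         "power": hits[m] / n_replicates,
                         "n_replicates": n_replicates})
    return pd.DataFrame(rows)
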