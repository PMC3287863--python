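"""Domain types and study-design construction for mixed case-control + trio samples.

The study design combines two sources of information about a binary disease
phenotype: unrelated case/control subjects, and complete case- or
control-parent trios.  Genotypes are additively coded minor-allele counts
(0/1/2), with ``MISSING`` (-1) as the sentinel for an unobserved genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: default MAF class boundaries: rare < 0.01 <= moderate <= 0.05 < common
DEFAULT_MAF_CUTOFFS = (0.01, 0.05)


class Role(str, Enum):
    UNRELATED = "unrelated"
    PARENT = "parent"
    OFFSPRING = "offspring"


class Status(str, Enum):
    """Per-SNP outcome of one association test."""

    OK = "ok"
    DEGENERATE = "degenerate"
    MONOMORPHIC = "monomorphic"
    NO_INFORMATIVE_TRIOS = "no_informative_trios"


class CCRule(str, Enum):
    """Which subjects form the case-control (logistic) arm.

    The default adds control-trio offspring to the classical
    probands + unrelated-controls subsample.
    """

    PROBANDS_UNREL_CONTROLS_CONTROL_OFFSPRING = (
        "probands_plus_unrelated_controls_plus_control_offspring"
    )
    PROBANDS_UNREL_CONTROLS = "probands_plus_unrelated_controls"
    ALL_UNRELATED = "all_unrelated"


@dataclass
class Individual:
    iid: str
    father_id: str | None = None
    mother_id: str | None = None
    affected: int | None = None  # 0/1, None = missing phenotype
    role: Role = Role.UNRELATED


@dataclass
class GenotypeMatrix:
    """Additively coded genotypes, individuals x SNPs; -1 marks missing."""

    values: np.ndarray
    snp_ids: list[str]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        n, s = self.values.shape
        if n != len(self.individual_ids) or s != len(self.snp_ids):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snp_ids)} SNPs"
            )
        valid = (self.values == MISSING) | (
            (self.values >= 0) & (self.values <= 2)
        )
        if not valid.all():
            bad = np.unique(self.values[~valid])
            raise ValueError(f"genotype entries outside {{0,1,2,{MISSING}}}: {bad}")
        self._row_index = {iid: i for i, iid in enumerate(self.individual_ids)}
        if len(self._row_index) != len(self.individual_ids):
            raise ValueError("duplicate individual id in genotype matrix")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def row(self, iid: str) -> np.ndarray:
        return self.values[self._row_index[iid]]

    def row_index(self, iid: str) -> int:
        return self._row_index[iid]

    def missing_fraction(self) -> np.ndarray:
        return (self.values == MISSING).mean(axis=0)


@dataclass
class Trio:
    """A complete father-mother-offspring unit, stored as row indices."""

    father: Individual
    mother: Individual
    offspring: Individual
    father_idx: int
    mother_idx: int
    offspring_idx: int


@dataclass
class SNPInfo:
    snp_id: str
    maf: float
    causal: bool = False
    beta: float = 0.0
    maf_class: str = "rare"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf {self.maf} outside [0, 0.5]")
        if not self.causal and self.beta != 0.0:
            raise ValueError("noncausal SNP must have beta = 0")


@dataclass
class AssociationResult:
    snp_id: str
    method: str
    statistic: float = np.nan
    p_value: float | None = None
    estimate: float | None = None
    se: float | None = None
    homogeneity_p: float | None = None
    status: Status = Status.OK
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.status == Status.OK) != (self.p_value is not None):
            raise ValueError("p_value must be present iff status is ok")


@dataclass
class CombinedSample:
    """Unrelated subjects plus complete trios over a shared genotype matrix."""

    genotypes: GenotypeMatrix
    individuals: dict[str, Individual]
    unrelated_idx: np.ndarray  # row indices of unrelated subjects
    trios: list[Trio]
    cc_rule: CCRule = CCRule.PROBANDS_UNREL_CONTROLS_CONTROL_OFFSPRING

    @property
    def n_unrelated(self) -> int:
        return len(self.unrelated_idx)

    @property
    def n_trios(self) -> int:
        return len(self.trios)

    @property
    def n_family_members(self) -> int:
        return 3 * self.n_trios

    def counts(self) -> tuple[int, int, int]:
        return (self.n_unrelated, self.n_trios, self.n_family_members)

    def founder_idx(self) -> np.ndarray:
        """Unrelated subjects plus trio parents (allele-frequency reference set)."""
        parents = [i for t in self.trios for i in (t.father_idx, t.mother_idx)]
        return np.concatenate(
            [np.asarray(self.unrelated_idx, dtype=int), np.asarray(parents, dtype=int)]
        ) if parents else np.asarray(self.unrelated_idx, dtype=int)

    def unrelated_phenotypes(self) -> np.ndarray:
        ids = [self.genotypes.individual_ids[i] for i in self.unrelated_idx]
        return np.array([self.individuals[i].affected for i in ids], dtype=float)

    def offspring_phenotypes(self) -> np.ndarray:
        return np.array([t.offspring.affected for t in self.trios], dtype=float)

    def trio_genotype_arrays(self, snp: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(father, mother, offspring) genotype vectors at one SNP, all trios."""
        g = self.genotypes.values
        f = g[[t.father_idx for t in self.trios], snp]
        m = g[[t.mother_idx for t in self.trios], snp]
        o = g[[t.offspring_idx for t in self.trios], snp]
        return f, m, o


def mendelian_valid(g_f: np.ndarray, g_m: np.ndarray, g_o: np.ndarray) -> np.ndarray:
    """Boolean mask of trios whose offspring genotype is compatible with
    Mendelian transmission from the parents.

    A homozygous parent must transmit its allele, so the offspring count is
    bounded by ``#hom-alt parents <= g_o <= 2 - #hom-ref parents``.
    """
    g_f = np.asarray(g_f)
    g_m = np.asarray(g_m)
    g_o = np.asarray(g_o)
    lo = (g_f == 2).astype(int) + (g_m == 2).astype(int)
    hi = 2 - (g_f == 0).astype(int) - (g_m == 0).astype(int)
    return (g_o >= lo) & (g_o <= hi)


def trio_usable_mask(sample: CombinedSample, snp: int) -> np.ndarray:
    """Trios usable at a SNP: all three genotypes observed and Mendel-consistent."""
    f, m, o = sample.trio_genotype_arrays(snp)
    observed = (f != MISSING) & (m != MISSING) & (o != MISSING)
    ok = observed.copy()
    ok[observed] = mendelian_valid(f[observed], m[observed], o[observed])
    return ok


def build_cc_subsample(
    sample: CombinedSample, rule: CCRule | None = None
) -> tuple[np.ndarray, np.ndarray, dict[int, int]]:
    """Rows and phenotypes for the logistic-regression (case-control) arm.

    Returns ``(indices, phenotypes, trio_of_row)`` where ``trio_of_row`` maps a
    genotype-row index of an included trio offspring to its trio's position in
    ``sample.trios`` (used to account for subjects shared between the two arms).
    Under the default rule the arm holds every trio offspring (affected
    probands and unaffected control offspring) plus the unrelated controls.
    """
    rule = rule or sample.cc_rule
    idx: list[int] = []
    y: list[int] = []
    trio_of_row: dict[int, int] = {}

    unrel_y = sample.unrelated_phenotypes()
    for i, row in enumerate(sample.unrelated_idx):
        pheno = unrel_y[i]
        if np.isnan(pheno):
            continue
        if rule != CCRule.ALL_UNRELATED and pheno != 0:
            continue  # unrelated cases enter only under the all_unrelated rule
        idx.append(int(row))
        y.append(int(pheno))

    for t_i, t in enumerate(sample.trios):
        pheno = t.offspring.affected
        if pheno is None:
            continue
        if rule == CCRule.PROBANDS_UNREL_CONTROLS and pheno != 1:
            continue  # no control offspring under the probands-only rule
        idx.append(t.offspring_idx)
        y.append(int(pheno))
        trio_of_row[t.offspring_idx] = t_i

    return np.asarray(idx, dtype=int), np.asarray(y, dtype=float), trio_of_row


def founder_maf(sample: CombinedSample, snp: int) -> float:
    """Minor-allele frequency at a SNP from founders only (unrelated + parents)."""
    g = sample.genotypes.values[sample.founder_idx(), snp]
    g = g[g != MISSING]
    if g.size == 0:
        return 0.0
    freq = g.sum() / (2.0 * g.size)
    return float(min(freq, 1.0 - freq))


def classify_maf(maf: float, cutoffs: tuple[float, float] = DEFAULT_MAF_CUTOFFS) -> str:
    rare_hi, moderate_hi = cutoffs
    if maf < rare_hi:
        return "rare"
    if maf <= moderate_hi:
        return "moderate"
    return "common"


def snp_summaries(
    sample: CombinedSample,
    cutoffs: tuple[float, float] = DEFAULT_MAF_CUTOFFS,
    truth: Mapping[str, "SNPInfo"] | None = None,
) -> list[SNPInfo]:
    """Per-SNP observed MAF (founders only) and MAF class.

    When generator truth is supplied, the causal flag and liability effect are
    carried over; the MAF reported is always the observed one.
    """
    out = []
    for j, snp_id in enumerate(sample.genotypes.snp_ids):
        maf = founder_maf(sample, j)
        causal, beta = False, 0.0
        if truth is not None and snp_id in truth:
            causal, beta = truth[snp_id].causal, truth[snp_id].beta
        out.append(
            SNPInfo(snp_id=snp_id, maf=maf, causal=causal, beta=beta,
                    maf_class=classify_maf(maf, cutoffs))
        )
    return out


RESULT_COLUMNS = [
    "snp_id", "method", "statistic", "p_value", "estimate", "se",
    "homogeneity_p", "status",
]


def results_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    rows = []
    extra_keys: list[str] = []
    results = list(results)
    for r in results:
        for k in r.extras:
            if k not in extra_keys:
                extra_keys.append(k)
    def _num(v):
        return np.nan if v is None else v

    for r in results:
        row = {
            "snp_id": r.snp_id,
            "method": r.method,
            "statistic": _num(r.statistic),
            "p_value": _num(r.p_value),
            "estimate": _num(r.estimate),
            "se": _num(r.se),
            "homogeneity_p": _num(r.homogeneity_p),
            "status": r.status.value,
        }
        for k in extra_keys:
            v = r.extras.get(k)
            row[k] = np.nan if v is None else v
        rows.append(row)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS + extra_keys)
    for col in df.columns:
        if col not in ("snp_id", "method", "status") and df[col].dtype == object:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_results(results: Sequence[AssociationResult], path) -> None:
    """One tab-separated row per SNP x method; missing fields as 'NA'."""
    if not results:
        raise ValueError("no results to write")
    results_to_frame(results).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
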