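"""Reading and writing pedigree + genotype files.

Pedigrees follow the six-column PED/FAM convention
(family, individual, father, mother, sex, phenotype).  Genotypes come either
from a tab-separated additive matrix (rows = individuals, columns = SNPs,
first column = individual id) or from a VCF whose GT fields are converted to
minor-allele counts.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    CombinedSample,
    GenotypeMatrix,
    Individual,
    Role,
)

logger = logging.getLogger(__name__)

_PED_MISSING_PARENT = {"0", "", ".", "NA"}


class PedigreeError(ValueError):
    pass


def _parse_ped(ped_path) -> dict[str, dict]:
    records: dict[str, dict] = {}
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(
                    f"{ped_path}:{lineno}: expected >= 6 columns, got {len(fields)}"
                )
            fam, iid, fid, mid, _sex, pheno = fields[:6]
            if iid in records:
                raise PedigreeError(f"{ped_path}:{lineno}: duplicate individual id {iid!r}")
            try:
                pheno_val = float(pheno)
            except ValueError as exc:
                raise PedigreeError(
                    f"{ped_path}:{lineno}: unparseable phenotype {pheno!r}"
                ) from exc
            records[iid] = {
                "family": fam,
                "father": None if fid in _PED_MISSING_PARENT else fid,
                "mother": None if mid in _PED_MISSING_PARENT else mid,
                "pheno_raw": pheno_val,
                "lineno": lineno,
            }
    return records


def _decode_phenotypes(records: dict[str, dict]) -> None:
    """Resolve the phenotype dialect for a whole file: PLINK-style 1/2
    (0 and -9 missing) when any code 2 is present, otherwise 0/1 (-9 missing)."""
    raw = {r["pheno_raw"] for r in records.values()}
    one_two = 2.0 in raw
    dialect = "1/2 (case=2)" if one_two else "0/1 (case=1)"
    logger.info("phenotype dialect detected: %s", dialect)
    for r in records.values():
        v = r["pheno_raw"]
        if one_two:
            r["affected"] = {1.0: 0, 2.0: 1}.get(v)  # 0/-9/other -> missing
        else:
            r["affected"] = {0.0: 0, 1.0: 1}.get(v)


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = df.replace({"NA": MISSING, ".": MISSING}).astype(float)
    arr = np.where(np.isnan(values.to_numpy()), MISSING, values.to_numpy()).astype(np.int16)
    return GenotypeMatrix(arr, snp_ids=list(df.columns), individual_ids=list(df.index))


def read_genotype_vcf(path) -> GenotypeMatrix:
    """Minor-allele counts from a VCF (requires cyvcf2)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    snp_ids, cols = [], []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        gt = np.asarray(var.gt_types, dtype=np.int16)  # 0/1/2, 3 = unknown
        gt[gt == 3] = MISSING
        cols.append(gt)
    arr = np.column_stack(cols) if cols else np.empty((len(ids), 0), dtype=np.int16)
    # recode to count the minor allele
    for j in range(arr.shape[1]):
        col = arr[:, j]
        obs = col[col != MISSING]
        if obs.size and obs.sum() > obs.size:  # alt frequency > 0.5
            col[col != MISSING] = 2 - col[col != MISSING]
    return GenotypeMatrix(arr, snp_ids=snp_ids, individual_ids=ids)


def read_ped(ped_path, genotype_path) -> CombinedSample:
    """Build a :class:`CombinedSample` from a pedigree and a genotype source.

    An individual with both parents present in the pedigree *and* genotyped
    becomes a trio offspring; everyone else (and every parent) is classified
    from the pedigree links.  Individuals with a missing phenotype are kept in
    the genotype matrix but excluded from testing by their ``affected=None``.
    """
    records = _parse_ped(ped_path)
    _decode_phenotypes(records)

    genotype_path = str(genotype_path)
    if genotype_path.endswith((".vcf", ".vcf.gz", ".bcf")):
        gmat = read_genotype_vcf(genotype_path)
    else:
        gmat = read_genotype_tsv(genotype_path)

    genotyped = set(gmat.individual_ids)
    individuals: dict[str, Individual] = {}
    for iid, rec in records.items():
        for pid in (rec["father"], rec["mother"]):
            if pid is not None and pid not in records:
                raise PedigreeError(
                    f"line {rec['lineno']}: {iid!r} references missing parent {pid!r}"
                )
        individuals[iid] = Individual(
            iid=iid, father_id=rec["father"], mother_id=rec["mother"],
            affected=rec["affected"],
        )

    trios = []
    parent_ids: set[str] = set()
    offspring_ids: set[str] = set()
    for iid, ind in individuals.items():
        if ind.father_id and ind.mother_id:
            if {iid, ind.father_id, ind.mother_id} <= genotyped:
                ind.role = Role.OFFSPRING
                offspring_ids.add(iid)
                parent_ids.update((ind.father_id, ind.mother_id))

    for iid in offspring_ids:
        ind = individuals[iid]
        father, mother = individuals[ind.father_id], individuals[ind.mother_id]
        father.role = Role.PARENT
        mother.role = Role.PARENT
        from .core import Trio

        trios.append(
            Trio(
                father=father, mother=mother, offspring=ind,
                father_idx=gmat.row_index(father.iid),
                mother_idx=gmat.row_index(mother.iid),
                offspring_idx=gmat.row_index(iid),
            )
        )
    trios.sort(key=lambda t: t.offspring.iid)

    unrelated = [
        gmat.row_index(iid)
        for iid in gmat.individual_ids
        if iid in individuals
        and individuals[iid].role == Role.UNRELATED
    ]
    return CombinedSample(
        genotypes=gmat,
        individuals=individuals,
        unrelated_idx=np.asarray(unrelated, dtype=int),
        trios=trios,
    )


def write_sample(sample: CombinedSample, prefix) -> tuple[Path, Path]:
    """Write a sample as ``<prefix>.ped`` + ``<prefix>.tsv`` (read_ped inverse)."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    gt_path = prefix.with_suffix(".tsv")

    fam_of: dict[str, str] = {}
    for t_i, t in enumerate(sample.trios):
        for ind in (t.father, t.mother, t.offspring):
            fam_of[ind.iid] = f"F{t_i + 1}"
    with open(ped_path, "w") as fh:
        for iid in sample.genotypes.individual_ids:
            ind = sample.individuals[iid]
            fam = fam_of.get(iid, f"U_{iid}")
            pheno = -9 if ind.affected is None else ind.affected
            fh.write(
                f"{fam}\t{iid}\t{ind.father_id or 0}\t{ind.mother_id or 0}\t0\t{pheno}\n"
            )

    df = pd.DataFrame(
        sample.genotypes.values,
        index=sample.genotypes.individual_ids,
        columns=sample.genotypes.snp_ids,
    ).replace(MISSING, "NA")
    df.index.name = "iid"
    df.to_csv(gt_path, sep="\t")
    return ped_path, gt_path
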