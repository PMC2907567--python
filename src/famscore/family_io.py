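"""Read and write PLINK-style PED/MAP files and sample-information tables.

PED dialect: whitespace-delimited, six leading columns (family, individual,
father, mother, sex, phenotype) followed by two allele columns per marker.
Sex is coded 1=male, 2=female, 0=unknown; phenotype 2=affected,
1=unaffected, 0 or -9=unknown; allele 0=missing. MAP files carry 3 or 4
columns (chromosome, marker ID, [genetic distance,] position).

Covariates PED cannot carry (age or birth order, IQ) travel in a separate
UTF-8 tab-separated table with a header row and columns ``family_id``,
``individual_id`` plus any of ``age``, ``birth_order``, ``iq``, ``sex``.
"""

from __future__ import annotations

import csv
from dataclasses import replace
from pathlib import Path

import numpy as np

from .datatypes import (
    MISSING_ALLELE,
    VALID_ALLELES,
    Individual,
    PedigreeDataset,
    SnpDef,
)
from .errors import ParseError, ValidationError

_SEX_FROM_PED = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}
_AFF_FROM_PED = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}
_AFF_TO_PED = {"affected": "2", "unaffected": "1", "unknown": "0"}


def _read_map(map_path: str | Path) -> list[SnpDef]:
    snps: list[SnpDef] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) not in (3, 4):
                raise ParseError(
                    f"MAP line has {len(fields)} fields, expected 3 or 4",
                    line=lineno,
                )
            # allele symbols are unknown until the PED is scanned; placeholders
            # are replaced below.
            snps.append(
                SnpDef(snp_id=fields[1], chrom=fields[0], allele_a="1", allele_b="2")
            )
    return snps


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> PedigreeDataset:
    """Parse a PED/MAP pair into a :class:`PedigreeDataset`.

    Allele symbols per marker are taken from the file itself (at most two
    distinct non-missing symbols per marker; monomorphic markers get a
    placeholder second allele). Raises :class:`ParseError` on malformed lines
    and :class:`ValidationError` on duplicate individuals or >2 alleles.
    """
    snps = _read_map(map_path)
    k = len(snps)
    if k == 0:
        raise ParseError(f"empty MAP file: {map_path}")

    individuals: list[Individual] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * k:
                raise ParseError(
                    f"PED line has {len(fields)} fields, expected {6 + 2 * k}",
                    line=lineno,
                )
            fam, iid, fid, mid, sex, pheno = fields[:6]
            alleles = fields[6:]
            for sym in alleles:
                if sym not in VALID_ALLELES and sym != MISSING_ALLELE:
                    raise ParseError(
                        f"invalid allele symbol {sym!r} for individual {iid!r}",
                        line=lineno,
                    )
            if sex not in _SEX_FROM_PED:
                raise ParseError(f"invalid sex code {sex!r}", line=lineno)
            if pheno not in _AFF_FROM_PED:
                raise ParseError(f"invalid phenotype code {pheno!r}", line=lineno)
            individuals.append(
                Individual(
                    family_id=fam,
                    individual_id=iid,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=_SEX_FROM_PED[sex],
                    affection=_AFF_FROM_PED[pheno],
                )
            )
            rows.append(alleles)
    if not individuals:
        raise ParseError(f"empty PED file: {ped_path}")

    geno = np.array(rows, dtype="U1").reshape(len(individuals), k, 2)

    # infer the observed allele pair per marker
    resolved: list[SnpDef] = []
    for j, snp in enumerate(snps):
        observed = sorted(set(geno[:, j, :].ravel()) - {MISSING_ALLELE})
        if len(observed) > 2:
            raise ValidationError(
                f"{snp.snp_id}: more than two alleles observed: {observed}"
            )
        if len(observed) == 2:
            a, b = observed
        elif len(observed) == 1:
            a = observed[0]
            b = "2" if a != "2" else "1"  # placeholder for monomorphic marker
        else:
            a, b = "1", "2"
        resolved.append(replace(snp, allele_a=a, allele_b=b))

    return PedigreeDataset(
        snps=resolved,
        individuals=individuals,
        genotypes=geno,
        provenance={"ped_path": str(ped_path), "map_path": str(map_path)},
    )


def write_ped_map(
    dataset: PedigreeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Emit a dataset as a PED/MAP pair re-readable by :func:`read_ped_map`.

    Missing genotypes are written as ``0 0``.
    """
    with open(map_path, "w") as fh:
        for snp in dataset.snps:
            fh.write(f"{snp.chrom}\t{snp.snp_id}\t0\t0\n")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(dataset.individuals):
            lead = [
                ind.family_id,
                ind.individual_id,
                ind.father_id or "0",
                ind.mother_id or "0",
                _SEX_TO_PED[ind.sex],
                _AFF_TO_PED[ind.affection],
            ]
            alleles = dataset.genotypes[i].ravel().tolist()
            fh.write("\t".join(lead + alleles) + "\n")


_SAMPLE_KEYS = ("family_id", "individual_id")
_SAMPLE_OPTIONAL = ("birth_order", "age", "iq", "sex")


def read_sample_info(tsv_path: str | Path, dataset: PedigreeDataset) -> PedigreeDataset:
    """Attach sample-information covariates to a dataset by (family, individual).

    Returns a new dataset; rows referencing unknown individuals are recorded
    in ``dataset.warnings`` rather than raising. If both ``age`` and
    ``birth_order`` columns are present, ``age`` wins and sets the dataset's
    age semantics.
    """
    out = dataset.copy()
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        for key in _SAMPLE_KEYS:
            if key not in cols:
                raise ValidationError(f"sample-info table lacks column {key!r}")
        has_age = "age" in cols
        has_order = "birth_order" in cols
        if has_age:
            out.age_semantics = "age"
        elif has_order:
            out.age_semantics = "birth_order"
        for rowno, row in enumerate(reader, start=2):
            key = (row["family_id"], row["individual_id"])
            try:
                i = out.row(*key)
            except KeyError:
                out.warnings.append(
                    f"sample-info row {rowno}: unknown individual {key}"
                )
                continue
            ind = out.individuals[i]
            ordinal_col = "age" if has_age else ("birth_order" if has_order else None)
            if ordinal_col and row.get(ordinal_col, "").strip():
                try:
                    ind.birth_order_or_age = float(row[ordinal_col])
                except ValueError:
                    raise ValidationError(
                        f"sample-info row {rowno}: non-numeric {ordinal_col} "
                        f"{row[ordinal_col]!r}"
                    )
            if "iq" in cols and row.get("iq", "").strip():
                try:
                    ind.iq = float(row["iq"])
                except ValueError:
                    raise ValidationError(
                        f"sample-info row {rowno}: non-numeric iq {row['iq']!r}"
                    )
            if "sex" in cols and row.get("sex", "").strip():
                sex = row["sex"].strip().lower()
                if sex in ("1", "m", "male"):
                    ind.sex = "male"
                elif sex in ("2", "f", "female"):
                    ind.sex = "female"
                else:
                    ind.sex = "unknown"
    return out


def write_sample_info(dataset: PedigreeDataset, tsv_path: str | Path) -> None:
    """Write covariates (age/birth order, IQ, sex) as a sample-info TSV."""
    ordinal_col = "age" if dataset.age_semantics == "age" else "birth_order"
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["family_id", "individual_id", "sex", ordinal_col, "iq"])
        for ind in dataset.individuals:
            writer.writerow(
                [
                    ind.family_id,
                    ind.individual_id,
                    _SEX_TO_PED[ind.sex],
                    "" if ind.birth_order_or_age is None else ind.birth_order_or_age,
                    "" if ind.iq is None else ind.iq,
                ]
            )
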