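"""Core data model: SNP definitions, individuals and nuclear-family genotype datasets.

Genotypes are unordered allele pairs stored in a dense ``(n_individuals,
n_snps, 2)`` array of single-character allele symbols, with ``"0"`` marking a
missing allele. A genotype is treated as missing if either of its alleles is
missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import ValidationError

MISSING_ALLELE = "0"
#: allele symbols accepted on input: bases plus PLINK-style numeric coding
VALID_ALLELES = frozenset({"A", "C", "G", "T", "1", "2"})

SEX_LABELS = ("male", "female", "unknown")
AFFECTION_LABELS = ("affected", "unaffected", "unknown")


@dataclass(frozen=True)
class SnpDef:
    """A biallelic marker, optionally annotated with its risk-score coding.

    ``risk_allele`` is the allele associated with disease, ``mode`` the
    inheritance coding used when scoring (``"additive"`` counts risk alleles
    0/1/2; ``"recessive"`` awards 2 points to risk-allele homozygotes and 0
    otherwise), and ``risk_freq`` the population frequency of the risk allele.
    The three may be left unset for markers read from a MAP file before a
    score model is attached.
    """

    snp_id: str
    chrom: str
    allele_a: str
    allele_b: str
    risk_allele: str | None = None
    mode: str | None = None
    risk_freq: float | None = None

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValidationError(
                f"{self.snp_id}: alleles must differ, got {self.allele_a!r} twice"
            )
        if self.risk_allele is not None and self.risk_allele not in (
            self.allele_a,
            self.allele_b,
        ):
            raise ValidationError(
                f"{self.snp_id}: risk allele {self.risk_allele!r} not in "
                f"{{{self.allele_a!r}, {self.allele_b!r}}}"
            )
        if self.mode is not None and self.mode not in ("additive", "recessive"):
            raise ValidationError(f"{self.snp_id}: unknown mode {self.mode!r}")
        if self.risk_freq is not None and not (0.0 <= self.risk_freq <= 1.0):
            raise ValidationError(
                f"{self.snp_id}: risk_freq {self.risk_freq} outside [0, 1]"
            )

    @property
    def other_allele(self) -> str:
        """The non-risk allele (requires risk_allele set)."""
        if self.risk_allele is None:
            raise ValidationError(f"{self.snp_id}: no risk allele configured")
        return self.allele_b if self.risk_allele == self.allele_a else self.allele_a


@dataclass
class Individual:
    family_id: str
    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affection: str = "unknown"
    birth_order_or_age: float | None = None
    iq: float | None = None
    is_index_case: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEX_LABELS:
            raise ValidationError(f"{self.individual_id}: bad sex {self.sex!r}")
        if self.affection not in AFFECTION_LABELS:
            raise ValidationError(
                f"{self.individual_id}: bad affection {self.affection!r}"
            )
        if self.is_index_case and self.affection != "affected":
            raise ValidationError(
                f"{self.individual_id}: index case must be affected"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.individual_id)


class PedigreeDataset:
    """Nuclear families with per-SNP genotypes and phenotype covariates.

    Parameters
    ----------
    snps
        Ordered marker definitions; column order of ``genotypes``.
    individuals
        Row order of ``genotypes``. Family IDs partition individuals into
        nuclear families; non-founders must reference parents present in the
        same family.
    genotypes
        ``(n, k, 2)`` array of allele symbols, ``"0"`` = missing.
    provenance
        Free-form metadata (source paths, simulation config, filters applied).
    age_semantics
        Whether ``birth_order_or_age`` holds an age (oldest child = maximum)
        or a birth order (oldest = minimum).
    """

    def __init__(
        self,
        snps: list[SnpDef],
        individuals: list[Individual],
        genotypes: np.ndarray,
        provenance: dict | None = None,
        age_semantics: str = "age",
        warnings: list[str] | None = None,
    ):
        genotypes = np.asarray(genotypes, dtype="U1")
        if genotypes.shape != (len(individuals), len(snps), 2):
            raise ValidationError(
                f"genotype array shape {genotypes.shape} does not match "
                f"{len(individuals)} individuals x {len(snps)} SNPs"
            )
        if age_semantics not in ("age", "birth_order"):
            raise ValidationError(f"bad age_semantics {age_semantics!r}")
        self.snps = list(snps)
        self.individuals = list(individuals)
        self.genotypes = genotypes
        self.provenance = dict(provenance or {})
        self.age_semantics = age_semantics
        self.warnings = list(warnings or [])
        self._validate()
        self._row_of = {ind.key: i for i, ind in enumerate(self.individuals)}
        self._snp_col = {s.snp_id: j for j, s in enumerate(self.snps)}

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        members: dict[str, set[str]] = {}
        for ind in self.individuals:
            if ind.key in seen:
                raise ValidationError(
                    f"duplicate individual {ind.individual_id!r} in family "
                    f"{ind.family_id!r}"
                )
            seen.add(ind.key)
            members.setdefault(ind.family_id, set()).add(ind.individual_id)
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in members[ind.family_id]:
                    raise ValidationError(
                        f"{ind.family_id}/{ind.individual_id}: parent {pid!r} "
                        "not present in family"
                    )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def row(self, family_id: str, individual_id: str) -> int:
        return self._row_of[(family_id, individual_id)]

    def snp_index(self, snp_id: str) -> int:
        return self._snp_col[snp_id]

    def families(self) -> dict[str, list[int]]:
        """Family ID -> row indices, preserving input order."""
        fams: dict[str, list[int]] = {}
        for i, ind in enumerate(self.individuals):
            fams.setdefault(ind.family_id, []).append(i)
        return fams

    def children(self, family_id: str) -> list[int]:
        """Rows of non-founder members of one family."""
        return [
            i
            for i in self.families()[family_id]
            if not self.individuals[i].is_founder
        ]

    def iter_trios(self) -> Iterator[tuple[int, int, int]]:
        """Yield (child_row, father_row, mother_row) for children with both
        parents listed."""
        for i, ind in enumerate(self.individuals):
            if ind.father_id is None or ind.mother_id is None:
                continue
            yield (
                i,
                self._row_of[(ind.family_id, ind.father_id)],
                self._row_of[(ind.family_id, ind.mother_id)],
            )

    # -- genotypes ---------------------------------------------------------

    def genotype(self, row: int, col: int) -> tuple[str, str] | None:
        """Unordered allele pair (sorted) or None if missing."""
        a, b = self.genotypes[row, col]
        if a == MISSING_ALLELE or b == MISSING_ALLELE:
            return None
        return (a, b) if a <= b else (b, a)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, k): True where the genotype is missing."""
        return (self.genotypes == MISSING_ALLELE).any(axis=2)

    def copy(self) -> "PedigreeDataset":
        return PedigreeDataset(
            snps=list(self.snps),
            individuals=[replace(ind) for ind in self.individuals],
            genotypes=self.genotypes.copy(),
            provenance=dict(self.provenance),
            age_semantics=self.age_semantics,
            warnings=list(self.warnings),
        )

    # -- comparison / export ----------------------------------------------

    def equals(self, other: "PedigreeDataset") -> bool:
        """Structural equality of markers, individuals and (unordered) genotypes.

        Provenance, warnings and covariates not representable in PED/MAP
        (iq, birth order) are compared too; callers wanting a PED-level
        comparison should strip those first.
        """
        if [s.snp_id for s in self.snps] != [s.snp_id for s in other.snps]:
            return False
        if self.individuals != other.individuals:
            return False
        return bool(
            (np.sort(self.genotypes, axis=2) == np.sort(other.genotypes, axis=2)).all()
        )

    def to_frame(self):
        """Individuals as a pandas DataFrame (one row each, no genotypes)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "family_id": [i.family_id for i in self.individuals],
                "individual_id": [i.individual_id for i in self.individuals],
                "father_id": [i.father_id for i in self.individuals],
                "mother_id": [i.mother_id for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "affection": [i.affection for i in self.individuals],
                "birth_order_or_age": [i.birth_order_or_age for i in self.individuals],
                "iq": [i.iq for i in self.individuals],
                "is_index_case": [i.is_index_case for i in self.individuals],
            }
        )
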