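"""Single-cell genotype-matrix analysis.

Works on cells x variants matrices with genotype codes WT / HET / HOM
(homozygous-or-hemizygous mutant) / MISSING and an optional per-cell 17p
copy state (2 or 1).  Core questions: what fraction of cells is biallelic,
which clones exist, is an apparent double hit true biallelic inactivation
or two-clone mosaicism, and does the cell composition explain the bulk VAF.

MISSING genotypes are conservatively treated as WT for the biallelic-cell
rule (raw fractions undercall in the presence of dropout); a closed-form
dropout-corrected estimate is reported alongside where applicable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GT_HET, GT_HOM, GT_MISSING, GT_WT, GENOTYPE_CODES

logger = logging.getLogger(__name__)


@dataclass
class CellGenotypeMatrix:
    """Rectangular genotype matrix; ``cn17p`` optional (2 = diploid, 1 =
    one 17p copy)."""

    genotypes: pd.DataFrame          # cells x variants, codes from the enum
    cn17p: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        bad = set(np.unique(self.genotypes.values)) - set(GENOTYPE_CODES)
        if bad:
            raise ValueError(f"unknown genotype codes: {sorted(bad)}")
        if self.cn17p is not None and len(self.cn17p) != len(self.genotypes):
            raise ValueError("cn17p must align with the genotype rows")

    @property
    def n_cells(self) -> int:
        return len(self.genotypes)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellGenotypeMatrix":
        """Build from a frame as written by the simulator (genotype columns
        plus an optional ``cn17p`` column)."""
        cn = df["cn17p"] if "cn17p" in df.columns else None
        geno = df.drop(columns=[c for c in ("cn17p", "clone") if c in df.columns])
        return cls(genotypes=geno, cn17p=cn)

    @classmethod
    def from_csv(cls, path) -> "CellGenotypeMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        df = self.genotypes.copy()
        if self.cn17p is not None:
            df["cn17p"] = self.cn17p
        df.to_csv(path)


def _mutant_mask(matrix: CellGenotypeMatrix) -> pd.DataFrame:
    """Boolean cells x variants: non-WT call (MISSING counts as WT)."""
    return matrix.genotypes.isin([GT_HET, GT_HOM])


def biallelic_cell_fraction(matrix: CellGenotypeMatrix) -> float:
    """Fraction of cells with both TP53 alleles hit.

    A cell is biallelic iff it carries two or more distinct mutant variants,
    or any HOM_or_HEMI call, or any mutant call together with a single 17p
    copy.  MISSING is treated as WT.
    """
    if matrix.n_cells == 0:
        raise ValueError("empty matrix")
    mut = _mutant_mask(matrix)
    two_variants = mut.sum(axis=1) >= 2
    any_hom = (matrix.genotypes == GT_HOM).any(axis=1)
    if matrix.cn17p is not None:
        hemi = mut.any(axis=1) & (np.asarray(matrix.cn17p) == 1)
    else:
        hemi = pd.Series(False, index=matrix.genotypes.index)
    return float((two_variants | any_hom | hemi).mean())


@dataclass
class CloneTable:
    clones: pd.DataFrame       # signature columns + n_cells + fraction
    n_unassigned: int          # cells in groups below the threshold
    min_cells: int


def decompose_clones(matrix: CellGenotypeMatrix, min_cells: int = 10
                     ) -> CloneTable:
    """Group cells by exact genotype signature (including cn17p when
    available); groups below ``min_cells`` are reported as unassigned."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    df = matrix.genotypes.copy()
    if matrix.cn17p is not None:
        df = df.assign(cn17p=np.asarray(matrix.cn17p))
    counts = df.groupby(list(df.columns), sort=False).size()
    counts = counts.sort_values(ascending=False)
    kept = counts[counts >= min_cells]
    dropped = int(counts[counts < min_cells].sum())
    clones = kept.reset_index(name="n_cells")
    clones["fraction"] = clones["n_cells"] / matrix.n_cells
    return CloneTable(clones=clones, n_unassigned=dropped, min_cells=min_cells)


@dataclass
class MosaicVerdict:
    verdict: str                      # mosaic | biallelic | indeterminate
    n_informative: int
    n_co_mutant: int
    expected_co_mutant: float         # under independence
    p_value: float
    co_mutant_fraction: float


def mosaic_vs_biallelic(matrix: CellGenotypeMatrix,
                        variant_pair: Sequence[str],
                        alpha: float = 0.01,
                        co_mutant_floor: float = 0.01,
                        min_informative: int = 20) -> MosaicVerdict:
    """Distinguish two-clone mosaicism from true compound-heterozygous
    biallelic inactivation for a pair of variants.

    Uses the 2x2 co-occurrence of mutant calls across informative cells
    (both genotypes non-MISSING).  *biallelic* requires a Fisher-exact
    excess of co-mutant cells over the independence expectation (p < alpha)
    together with a co-mutant fraction of at least ``co_mutant_floor``;
    *mosaic* when co-mutant cells do not exceed that expectation (mutant
    populations disjoint up to noise); otherwise *indeterminate*.
    """
    va, vb = variant_pair
    for v in (va, vb):
        if v not in matrix.genotypes.columns:
            raise ValueError(f"variant {v!r} not in matrix")
    informative = (~matrix.genotypes[[va, vb]].isin([GT_MISSING])).all(axis=1)
    sub = matrix.genotypes.loc[informative, [va, vb]]
    n = len(sub)
    a_mut = sub[va].isin([GT_HET, GT_HOM]).to_numpy()
    b_mut = sub[vb].isin([GT_HET, GT_HOM]).to_numpy()
    n_co = int((a_mut & b_mut).sum())
    if n < min_informative:
        logger.warning("only %d informative cells; verdict indeterminate", n)
        return MosaicVerdict("indeterminate", n, n_co, float("nan"),
                             float("nan"), float("nan"))
    expected = a_mut.mean() * b_mut.mean() * n
    table = [[n_co, int((a_mut & ~b_mut).sum())],
             [int((~a_mut & b_mut).sum()), int((~a_mut & ~b_mut).sum())]]
    _, p = stats.fisher_exact(table, alternative="greater")
    co_frac = n_co / n
    if p < alpha and n_co > expected and co_frac >= co_mutant_floor:
        verdict = "biallelic"
    elif n_co <= expected:
        verdict = "mosaic"
    else:
        verdict = "indeterminate"
    return MosaicVerdict(verdict, n, n_co, float(expected), float(p),
                         float(co_frac))


def reconcile_bulk(matrix: CellGenotypeMatrix,
                   observed_bulk_vafs: dict[str, float],
                   dropout: Optional[float] = None) -> pd.DataFrame:
    """Compare bulk VAFs against the VAF expected from the cell composition.

    Each cell is treated as a clone of fraction 1/n: HET contributes one
    mutant allele of two, HOM_or_HEMI two of two (or one of one when cn17p
    is 1), MISSING/WT none.  Returns per shared variant the expected VAF,
    the observed bulk VAF and the discrepancy (observed - expected).  With
    ``dropout`` given, a bias-corrected expectation is added: for diploid
    cells the call model loses mutant alleles only when both alleles drop
    (the cell reads MISSING, counted WT) — a het cell whose wild-type
    allele drops is called HOM_or_HEMI and counts double, offsetting the
    het cell whose mutant allele drops — so the expected undercount factor
    is (1 - dropout^2).
    """
    rows = []
    cn = (np.asarray(matrix.cn17p) if matrix.cn17p is not None
          else np.full(matrix.n_cells, 2))
    for v, bulk in observed_bulk_vafs.items():
        if v not in matrix.genotypes.columns:
            logger.warning("variant %r absent from matrix; skipped", v)
            continue
        g = matrix.genotypes[v].to_numpy()
        mut_alleles = np.where(g == GT_HOM, cn,
                               np.where(g == GT_HET, 1, 0))
        total_alleles = cn.sum()
        expected = float(mut_alleles.sum() / total_alleles)
        row = {"variant": v, "expected_vaf_from_cells": expected,
               "observed_bulk_vaf": float(bulk),
               "discrepancy": float(bulk) - expected}
        if dropout is not None and dropout > 0:
            row["expected_vaf_dropout_corrected"] = min(
                expected / (1.0 - dropout ** 2), 1.0)
            row["discrepancy_corrected"] = (float(bulk)
                                            - row["expected_vaf_dropout_corrected"])
        rows.append(row)
    return pd.DataFrame(rows)
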