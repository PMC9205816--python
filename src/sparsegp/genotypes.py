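"""Marker quality control and relationship-matrix construction.

Genotypes are allele dosages in {0, 1, 2} (count of the alternate allele)
with NaN for missing calls.  Two relationship matrices are supported:

* genomic ``G`` (VanRaden method 1 with observed allele frequencies),
* pedigree ``A`` (numerator relationship matrix, tabular method).

For analyses that combine a genotyped panel with ungenotyped historical
lines, :func:`block_diagonal_kinship` extends a kinship matrix with an
identity block, so the mixed model treats the extra lines as unrelated to
the panel and to one another.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "PedigreeTable",
    "filter_snps",
    "impute_missing",
    "compute_G",
    "compute_A",
    "block_diagonal_kinship",
]


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with optional missing calls (NaN)."""

    line_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # float array, entries in {0,1,2} or NaN

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0)) | (vals >= 0)):
            raise ValueError("dosages must be in {0,1,2} or NaN")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(float))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="line")

    @classmethod
    def read_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="line")
        return cls.from_frame(df)

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Import GT calls from a VCF as alt-allele dosages.

        Multi-allelic sites are skipped (count is logged).  Requires cyvcf2.
        """
        from cyvcf2 import VCF  # optional dependency

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        marker_ids: list[str] = []
        rows: list[np.ndarray] = []
        n_multi = 0
        for var in vcf:
            if len(var.ALT) != 1:
                n_multi += 1
                continue
            # gt_types: 0=hom ref, 1=het, 2=hom alt(cyvcf2: 3), 2=unknown
            gts = var.genotype.array()[:, :2].astype(float)
            gts[gts < 0] = np.nan
            dos = gts.sum(axis=1)
            marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            rows.append(dos)
        if n_multi:
            logger.info("skipped %d multi-allelic sites", n_multi)
        dosages = np.column_stack(rows) if rows else np.empty((len(samples), 0))
        return cls(samples, marker_ids, dosages)


@dataclass
class KinshipMatrix:
    """Symmetric lines x lines relationship matrix (genomic or pedigree)."""

    line_ids: list[str]
    values: np.ndarray
    kind: str = "genomic"  # {"genomic", "pedigree"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square and match line_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        if self.kind not in ("genomic", "pedigree"):
            raise ValueError(f"unknown kinship kind {self.kind!r}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def index_of(self, line_ids) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.line_ids)}
        try:
            return np.array([pos[l] for l in line_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"line {e.args[0]!r} not in kinship matrix") from None

    def stabilized(self, jitter: float = 1e-6, blend: float = 0.0) -> "KinshipMatrix":
        """Return a positive-definite version: optional identity blend plus
        a small diagonal jitter (applied before any factorization)."""
        v = self.values
        if blend > 0:
            v = (1.0 - blend) * v + blend * np.eye(self.n_lines)
        v = v + jitter * np.eye(self.n_lines)
        return KinshipMatrix(list(self.line_ids), v, self.kind)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids).to_csv(
            path, sep="\t", index_label="line"
        )

    @classmethod
    def read_tsv(cls, path, kind: str = "genomic") -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col="line")
        return cls(list(map(str, df.index)), df.to_numpy(float), kind)


@dataclass
class PedigreeTable:
    """Records of (individual, parent1, parent2); unknown parents are None."""

    records: list[tuple[str, str | None, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individuals in pedigree")

    @property
    def individuals(self) -> list[str]:
        return [r[0] for r in self.records]

    def parents_of(self) -> dict[str, tuple[str | None, str | None]]:
        return {ind: (p1, p2) for ind, p1, p2 in self.records}

    def topological_order(self) -> list[str]:
        """Return individuals ordered so parents precede offspring.

        Parents never listed as individuals are treated as founders and
        prepended.  Raises on a cycle, reporting the offending chain.
        """
        parents = self.parents_of()
        known = set(parents)
        founders: list[str] = []
        seen_f: set[str] = set()
        for _, p1, p2 in self.records:
            for p in (p1, p2):
                if p is not None and p not in known and p not in seen_f:
                    founders.append(p)
                    seen_f.add(p)
        order: list[str] = list(founders)
        state: dict[str, int] = {f: 2 for f in founders}  # 0 new, 1 active, 2 done

        def visit(node: str, chain: list[str]) -> None:
            st = state.get(node, 0)
            if st == 2:
                return
            if st == 1:
                cyc = chain[chain.index(node):] + [node]
                raise ValueError(f"pedigree cycle detected: {' -> '.join(cyc)}")
            state[node] = 1
            chain.append(node)
            for p in parents.get(node, (None, None)):
                if p is not None:
                    visit(p, chain)
            chain.pop()
            state[node] = 2
            order.append(node)

        for ind in parents:
            visit(ind, [])
        return order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["id", "parent1", "parent2"])

    def write_tsv(self, path) -> None:
        df = self.to_frame().fillna(".")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "PedigreeTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        recs = [
            (r.id, None if r.parent1 in (".", None) else r.parent1,
             None if r.parent2 in (".", None) else r.parent2)
            for r in df.itertuples()
        ]
        return cls(recs)


# ---------------------------------------------------------------------------
# Marker QC


def _allele_freq(dosages: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per marker, ignoring missing calls."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(dosages, axis=0) / 2.0


def filter_snps(
    g: GenotypeMatrix, max_missing: float = 0.20, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Remove markers with more than ``max_missing`` missing calls or a
    minor allele frequency below ``min_maf`` (computed on non-missing calls).

    Ties at either threshold are kept, matching the exclusion of markers
    with *more than* 20% missing and MAF *less than* 5%.  Marker order is
    preserved; the line set is unchanged.
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    miss = np.isnan(g.dosages).mean(axis=0)
    p = _allele_freq(g.dosages)
    maf = np.minimum(p, 1.0 - p)
    with np.errstate(invalid="ignore"):
        keep = (miss <= max_missing) & (np.nan_to_num(maf, nan=-1.0) >= min_maf)
    if not keep.any():
        warnings.warn("no markers passed QC thresholds", UserWarning, stacklevel=2)
    return GenotypeMatrix(
        list(g.line_ids),
        [m for m, k in zip(g.marker_ids, keep) if k],
        g.dosages[:, keep],
    )


def impute_missing(g: GenotypeMatrix, method: str = "marker_mean") -> GenotypeMatrix:
    """Fill missing dosages; only ``marker_mean`` is implemented.

    Non-missing entries are left untouched; fractional fills are permitted
    downstream (they only enter centered dosage products).
    """
    if method != "marker_mean":
        raise ValueError(f"unknown imputation method {method!r}")
    d = g.dosages.copy()
    all_missing = np.isnan(d).all(axis=0)
    if all_missing.any():
        bad = [m for m, b in zip(g.marker_ids, all_missing) if b]
        raise ValueError(f"markers with no observed calls cannot be imputed: {bad[:5]}")
    if not np.isnan(d).any():
        return g
    means = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = means[idx[1]]
    return GenotypeMatrix(list(g.line_ids), list(g.marker_ids), d)


# ---------------------------------------------------------------------------
# Relationship matrices


def compute_G(g: GenotypeMatrix, allele_freq: np.ndarray | None = None) -> KinshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G = W W' / (2 sum_j p_j (1 - p_j)) with W the dosage matrix centered by
    twice the allele frequency — observed panel frequencies by default, or
    base-population frequencies via ``allele_freq`` (the reference in which
    E[G] equals the pedigree relationship).  The mean diagonal is
    approximately 1 plus the mean inbreeding coefficient of the panel.
    """
    if np.isnan(g.dosages).any():
        raise ValueError("impute missing dosages before computing G")
    if allele_freq is not None:
        p = np.asarray(allele_freq, dtype=float)
        if p.shape != (g.n_markers,):
            raise ValueError("allele_freq must have one entry per marker")
    else:
        p = _allele_freq(g.dosages)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers are monomorphic; G denominator is zero")
    W = g.dosages - 2.0 * p
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    return KinshipMatrix(list(g.line_ids), G, "genomic")


def compute_A(ped: PedigreeTable) -> KinshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    Founders (individuals with no recorded parents, or parents never listed
    as individuals) are assumed unrelated and non-inbred.
    """
    order = ped.topological_order()
    parents = ped.parents_of()
    idx = {ind: i for i, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, ind in enumerate(order):
        p1, p2 = parents.get(ind, (None, None))
        i1 = idx[p1] if p1 is not None else None
        i2 = idx[p2] if p2 is not None else None
        for j in range(i):
            a = 0.0
            if i1 is not None:
                a += 0.5 * A[j, i1]
            if i2 is not None:
                a += 0.5 * A[j, i2]
            A[i, j] = A[j, i] = a
        if i1 is not None and i2 is not None:
            A[i, i] = 1.0 + 0.5 * A[i1, i2]
        else:
            A[i, i] = 1.0
    return KinshipMatrix(order, A, "pedigree")


def block_diagonal_kinship(k1: KinshipMatrix, extra_line_ids) -> KinshipMatrix:
    """Extend a kinship matrix with an identity block for ungenotyped lines.

    The extra lines get unit diagonal and zero covariance with the original
    panel and with each other (the combined-dataset convention when only the
    overlapping lines carry marker information).
    """
    extra = list(extra_line_ids)
    if not extra:
        return k1
    overlap = set(extra) & set(k1.line_ids)
    if overlap:
        raise ValueError(f"extra lines overlap the kinship panel: {sorted(overlap)[:5]}")
    if len(set(extra)) != len(extra):
        raise ValueError("duplicate extra line ids")
    n1, n2 = k1.n_lines, len(extra)
    v = np.zeros((n1 + n2, n1 + n2))
    v[:n1, :n1] = k1.values
    v[n1:, n1:] = np.eye(n2)
    return KinshipMatrix(list(k1.line_ids) + extra, v, k1.kind)
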