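"""Distance matrices (Mash and Rogers), PHYLIP I/O, and the Mantel test.

Two independent routes to a pairwise genetic distance are supported:
sketch-based Mash distances between accessions' k-mer sets, and Rogers'
genetic distance between SNP-array genotypes. Both end up in the same
labeled symmetric ``DistanceMatrix`` container; the Mantel permutation test
quantifies the agreement between the two routes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sketch import Sketch, jaccard, mash_distance

__all__ = [
    "DistanceMatrix",
    "GenotypeMatrix",
    "MantelResult",
    "pairwise_mash",
    "rogers_distance",
    "rogers_matrix",
    "mantel_test",
    "write_phylip",
    "read_phylip",
]


@dataclass
class DistanceMatrix:
    """Labeled symmetric non-negative matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy condensed) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def mean_offdiagonal(self) -> float:
        return float(self.condensed().mean())

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns aligned to ``labels`` (by name)."""
        missing = set(labels).symmetric_difference(self.labels)
        if missing:
            raise ValueError(f"label sets differ: {sorted(missing)}")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)


def pairwise_mash(sketches: Sequence[Sketch]) -> DistanceMatrix:
    """All-pairs Mash distance matrix, labels in input order."""
    n = len(sketches)
    labels = [sk.name for sk in sketches]
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        try:
            est, _, _ = jaccard(sketches[i], sketches[j])
        except ValueError as exc:
            raise ValueError(
                f"incompatible sketches {labels[i]!r} vs {labels[j]!r}: {exc}"
            ) from exc
        d = mash_distance(est, sketches[i].k)
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels, vals, kind="mash")


# ---------------------------------------------------------------------------
# Genotypes and Rogers' distance
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic markers; codes 0/1/2 with NaN for missing."""

    accessions: list[str]
    markers: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.float64)
        if self.codes.shape != (len(self.accessions), len(self.markers)):
            raise ValueError("genotype matrix shape does not match labels")
        finite = np.isfinite(self.codes)
        if not np.isin(self.codes[finite], (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")
        if not finite.any(axis=1).all():
            bad = [a for a, row in zip(self.accessions, finite) if not row.any()]
            raise ValueError(f"accessions with no non-missing genotype: {bad}")

    def row(self, accession: str) -> np.ndarray:
        return self.codes[self.accessions.index(accession)]

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        df = pd.DataFrame(self.codes, index=self.accessions, columns=self.markers)
        df.to_csv(path, sep="\t", na_rep="NA", index_label="accession")

    @classmethod
    def from_tsv(cls, path: str) -> "GenotypeMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=np.float64))


def rogers_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Rogers' genetic distance between two genotype rows.

    Codes are converted to within-individual allele frequencies
    p in {0, 0.5, 1}; each marker non-missing in both rows contributes
    sqrt(((p-q)^2 + ((1-p)-(1-q))^2)/2) = |p - q|, and the distance is the
    mean contribution over the jointly non-missing markers.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("genotype rows must cover the same marker set")
    both = np.isfinite(a) & np.isfinite(b)
    if not both.any():
        raise ValueError("no shared (jointly non-missing) markers")
    return float(np.abs(a[both] - b[both]).mean() / 2.0)


def rogers_matrix(genotypes: GenotypeMatrix) -> DistanceMatrix:
    """All-pairs Rogers' distance with pairwise-complete marker sets."""
    n = len(genotypes.accessions)
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        vals[i, j] = vals[j, i] = rogers_distance(
            genotypes.codes[i], genotypes.codes[j]
        )
    return DistanceMatrix(list(genotypes.accessions), vals, kind="rogers")


# ---------------------------------------------------------------------------
# Mantel permutation test
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p: float
    permutations: int
    n: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise ValueError("zero variance in distance matrix entries")
    return float((xc * yc).sum() / denom)


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """One-sided Mantel test (Pearson r over upper triangles).

    Matrices are aligned by label (never by position). The null distribution
    jointly permutes rows and columns of ``d2``; the one-sided p-value is
    (#{r_perm >= r_obs} + 1) / (permutations + 1).
    """
    if d1.n < 3:
        raise ValueError("Mantel test requires at least 3 taxa")
    d2a = d2.reorder(d1.labels)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    r_obs = _pearson(x, d2a.values[iu])
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(permutations)])
    permuted = d2a.values[perms[:, :, None], perms[:, None, :]]  # (P, n, n)
    ys = permuted[:, iu[0], iu[1]]  # (P, npairs)
    xc = x - x.mean()
    yc = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum(axis=1))
    r_perm = (yc @ xc) / denom
    p = (int((r_perm >= r_obs - 1e-15).sum()) + 1) / (permutations + 1)
    return MantelResult(r=r_obs, p=p, permutations=permutations, n=n)


# ---------------------------------------------------------------------------
# PHYLIP square distance-matrix I/O
# ---------------------------------------------------------------------------


def write_phylip(matrix: DistanceMatrix, path: str) -> None:
    """Write the standard square PHYLIP format (10-character name field)."""
    short = [l[:10] for l in matrix.labels]
    if len(set(short)) != len(short):
        dupes = sorted({s for s in short if short.count(s) > 1})
        raise ValueError(
            f"names are ambiguous after 10-character truncation: {dupes}"
        )
    with open(path, "wt") as fh:
        fh.write(f"{matrix.n}\n")
        for name, row in zip(short, matrix.values):
            vals = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{name:<10}{vals}\n")


def read_phylip(path: str, kind: str = "generic") -> DistanceMatrix:
    with open(path, "rt") as fh:
        header = fh.readline()
        try:
            n = int(header.split()[0])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed PHYLIP header {header!r}") from exc
        labels: list[str] = []
        rows: list[list[float]] = []
        for i in range(n):
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: expected {n} rows, found {i}")
            name = line[:10].strip()
            vals = [float(v) for v in line[10:].split()]
            if len(vals) != n:
                raise ValueError(
                    f"{path}: row {name!r} has {len(vals)} values, expected {n}"
                )
            labels.append(name)
            rows.append(vals)
    values = np.asarray(rows)
    values = (values + values.T) / 2.0  # absorb 6-decimal rounding asymmetry
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, values, kind=kind)


def to_long_dataframe(matrix: DistanceMatrix):
    """Long-format (nameA, nameB, distance) export of the upper triangle."""
    import pandas as pd

    recs = [
        (matrix.labels[i], matrix.labels[j], matrix.values[i, j])
        for i, j in itertools.combinations(range(matrix.n), 2)
    ]
    return pd.DataFrame(recs, columns=["name_a", "name_b", "distance"])
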