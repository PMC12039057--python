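"""Structure-side similarity: SMILES -> circular fingerprints -> Tanimoto
matrix -> hierarchical dendrogram and canonical leaf ordering.

The leaf order is what arranges spectra on the heatmap axes.  Linkage is
average (UPGMA) on 1 - Tanimoto by default; the choice is configurable and
recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "SkeletonRecord",
    "SimilarityMatrix",
    "fingerprint",
    "tanimoto",
    "smiles_to_smarts",
    "tanimoto_matrix",
    "build_dendrogram",
    "build_skeleton_records",
]

FP_BITS = 2048
FP_RADIUS = 2


def _mol_from_smiles(smiles: str, context: str = ""):
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        where = f" ({context})" if context else ""
        raise ValueError(f"unparsable SMILES{where}: {smiles!r}")
    return mol


def fingerprint(smiles: str, radius: int = FP_RADIUS, n_bits: int = FP_BITS) -> np.ndarray:
    """Morgan (circular) fingerprint as a 0/1 vector; radius 2, 2048 bits."""
    from rdkit.Chem import rdFingerprintGenerator

    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b|; two empty vectors count as identical (1.0)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def smiles_to_smarts(smiles: str) -> str:
    """SMARTS pattern derived from a SMILES; matches its own source molecule."""
    from rdkit import Chem

    mol = _mol_from_smiles(smiles)
    return Chem.MolToSmarts(mol)


@dataclass
class SkeletonRecord:
    """A named scaffold with its SMILES, derived SMARTS and fingerprint."""

    name: str
    smiles: str
    smarts: str = ""
    fingerprint: np.ndarray = field(default_factory=lambda: np.zeros(FP_BITS, dtype=np.uint8))


def build_skeleton_records(table: dict[str, str]) -> list[SkeletonRecord]:
    """From a name -> SMILES mapping, derive SMARTS and fingerprints."""
    records = []
    for name in table:
        smiles = table[name]
        try:
            records.append(
                SkeletonRecord(
                    name=name,
                    smiles=smiles,
                    smarts=smiles_to_smarts(smiles),
                    fingerprint=fingerprint(smiles),
                )
            )
        except ValueError as exc:
            raise ValueError(f"skeleton {name!r}: {exc}") from exc
    return records


@dataclass
class SimilarityMatrix:
    """Labelled symmetric similarity matrix with a dendrogram leaf order."""

    labels: list[str]
    values: np.ndarray
    leaf_order: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def reordered(self) -> "SimilarityMatrix":
        """Rows/columns permuted into leaf order."""
        order = self.leaf_order or self.labels
        idx = [self.labels.index(l) for l in order]
        return SimilarityMatrix(
            labels=list(order),
            values=self.values[np.ix_(idx, idx)],
            leaf_order=list(order),
            metadata=dict(self.metadata),
        )


def tanimoto_matrix(records: list[SkeletonRecord]) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix over skeleton fingerprints."""
    n = len(records)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tanimoto(
                records[i].fingerprint, records[j].fingerprint
            )
    return SimilarityMatrix(labels=[r.name for r in records], values=values)


class _Node:
    __slots__ = ("left", "right", "label", "height")

    def __init__(self, label=None, left=None, right=None, height=0.0):
        self.label = label
        self.left = left
        self.right = right
        self.height = height

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.left.leaves() + self.right.leaves()


def _canonicalize(node: _Node) -> None:
    """Lighter (fewer-leaf) subtree first; ties by smallest leaf label."""
    if node.is_leaf:
        return
    _canonicalize(node.left)
    _canonicalize(node.right)
    def key(n: _Node):
        leaves = n.leaves()
        return (len(leaves), min(leaves))
    if key(node.right) < key(node.left):
        node.left, node.right = node.right, node.left


def _newick(node: _Node, parent_height: float | None = None) -> str:
    length = "" if parent_height is None else f":{max(parent_height - node.height, 0.0):.6f}"
    if node.is_leaf:
        return f"{node.label}{length}"
    inner = ",".join(_newick(c, node.height) for c in (node.left, node.right))
    return f"({inner}){length}"


def build_dendrogram(
    matrix: SimilarityMatrix, method: str = "average"
) -> tuple[str, list[str]]:
    """Agglomerative clustering on distance 1 - similarity.

    Returns (newick tree, leaf order).  The canonical flip rule (lighter
    subtree first, ties by smallest leaf label) makes the leaf order
    deterministic under label-order permutation.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("dendrogram needs at least 2 labels")
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method=method)

    nodes: dict[int, _Node] = {
        i: _Node(label=matrix.labels[i]) for i in range(n)
    }
    for k, (a, b, height, _) in enumerate(linkage):
        nodes[n + k] = _Node(
            left=nodes[int(a)], right=nodes[int(b)], height=float(height)
        )
    root = nodes[n + len(linkage) - 1]
    _canonicalize(root)
    leaf_order = root.leaves()
    return _newick(root) + ";", leaf_order
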