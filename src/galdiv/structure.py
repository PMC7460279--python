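"""Population structure: genetic distances, classical MDS, neighbor-joining.

* Identity-by-state (IBS) distance between individuals: over markers typed
  in both, per-marker allele sharing (2 - |g_a - g_b|)/2 is averaged and the
  distance is 1 minus that mean (pairwise deletion of missing calls).
* Reynolds distance between breeds, from allele-frequency divergence:
  theta = sum_l 2 (p_x - p_y)^2 / sum_l 2 (1 - p_x p_y - q_x q_y),
  the coancestry-based short-term drift distance (large-sample estimator;
  optionally linearized as -ln(1 - theta)).
* Classical MDS (principal coordinates): eigendecomposition of the
  double-centred Gram matrix; axes with negative eigenvalues are dropped.
* Neighbor-joining on any distance matrix, with deterministic tie-breaking
  (first minimal pair in label order), Newick serialization, and negative
  branch-length clamping.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.tree import TreeNode

from .errors import GaldivError
from .io import MISSING, GenotypeDataset
from .qc import allele_frequencies


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with labels; level is individual or breed."""

    labels: list[str]
    d: np.ndarray
    level: str = "individual"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise GaldivError("distance matrix shape does not match labels")
        finite = np.isfinite(self.d)
        if not np.allclose(self.d[finite], self.d.T[finite]):
            raise GaldivError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise GaldivError("distance matrix diagonal must be zero")
        if (self.d[finite] < -1e-12).any():
            raise GaldivError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class MDSResult:
    coordinates: pd.DataFrame  # labels x components
    eigenvalues: np.ndarray  # descending, the retained (positive) ones


def ibs_distance(ds: GenotypeDataset, allow_missing_pairs: bool = False) -> DistanceMatrix:
    """1 - mean allele sharing over markers typed in both individuals."""
    if ds.n_samples < 2:
        raise GaldivError("IBS distance needs at least 2 samples")
    g = ds.calls
    valid = (g != MISSING).astype(np.float64)
    ind = [
        ((g == code) & (g != MISSING)).astype(np.float64) for code in (0, 1, 2)
    ]
    # total |g_a - g_b| over shared markers, via one-hot cross-products
    diff1 = ind[0] @ ind[1].T + ind[1] @ ind[0].T + ind[1] @ ind[2].T + ind[2] @ ind[1].T
    diff2 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    shared = valid @ valid.T
    no_shared = shared == 0
    if no_shared.any() and not allow_missing_pairs:
        i, j = np.argwhere(no_shared)[0]
        raise GaldivError(
            f"samples {ds.samples['id'].iloc[i]!r} and "
            f"{ds.samples['id'].iloc[j]!r} share no typed markers "
            f"(pass allow_missing_pairs=True)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (diff1 + 2.0 * diff2) / (2.0 * shared)
    d = np.where(no_shared, np.nan, d).astype(float)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry of the accumulation
    return DistanceMatrix(labels=ds.samples["id"].tolist(), d=d, level="individual")


def classical_mds(D: DistanceMatrix, k: int = 2) -> MDSResult:
    """Principal-coordinates embedding of a distance matrix.

    B = -1/2 J D^2 J is eigendecomposed; coordinates are the top-k
    eigenvectors scaled by sqrt(eigenvalue).  If fewer than k positive
    eigenvalues exist, k is reduced with a warning.
    """
    if k < 1:
        raise GaldivError("k must be >= 1")
    d = D.d
    if np.isnan(d).any():
        raise GaldivError("distance matrix contains undefined entries")
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-12 if n else 0.0
    npos = int((vals > tol).sum())
    k_eff = min(k, npos)
    if k_eff < k:
        warnings.warn(
            f"only {k_eff} positive eigenvalue(s); returning {k_eff} components",
            stacklevel=2,
        )
    if k_eff == 0:
        coords = np.zeros((n, k))
        return MDSResult(
            coordinates=pd.DataFrame(
                coords, index=D.labels, columns=[f"C{i+1}" for i in range(k)]
            ),
            eigenvalues=np.zeros(k),
        )
    coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
    return MDSResult(
        coordinates=pd.DataFrame(
            coords, index=D.labels, columns=[f"C{i+1}" for i in range(k_eff)]
        ),
        eigenvalues=vals[:k_eff],
    )


def breed_average_mds(
    ds: GenotypeDataset, k: int = 2, average_first: bool = False
) -> MDSResult:
    """Breed-level MDS summary of the IBS matrix.

    Default embeds individuals then averages coordinates per breed;
    ``average_first`` instead averages the between-breed distances before
    embedding.
    """
    D = ibs_distance(ds)
    breeds = ds.samples["breed"].to_numpy()
    labels = ds.breeds
    if average_first:
        nb = len(labels)
        davg = np.zeros((nb, nb))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    block = D.d[np.ix_(breeds == x, breeds == y)]
                    davg[i, j] = davg[j, i] = float(block.mean())
        res = classical_mds(DistanceMatrix(labels, davg, level="breed"), k)
        return res
    res = classical_mds(D, k)
    coords = res.coordinates.copy()
    coords["breed"] = breeds
    avg = coords.groupby("breed", sort=False).mean()
    avg = avg.loc[labels]
    return MDSResult(coordinates=avg, eigenvalues=res.eigenvalues)


def reynolds_distance(
    ds: GenotypeDataset, groups: list[str] | None = None, linearized: bool = False
) -> DistanceMatrix:
    """Reynolds coancestry distance between breeds from allele frequencies.

    Loci with an undefined frequency in either breed are skipped pair-wise.
    """
    labels = groups if groups is not None else ds.breeds
    freqs = {}
    for breed in labels:
        p = allele_frequencies(ds, group=breed)
        if np.isnan(p).all():
            raise GaldivError(f"breed {breed!r} has no defined allele frequencies")
        if (ds.samples["breed"] == breed).sum() < 2:
            raise GaldivError(f"breed {breed!r} needs at least 2 samples")
        freqs[breed] = p
    nb = len(labels)
    d = np.zeros((nb, nb))
    for i in range(nb):
        for j in range(i + 1, nb):
            px, py = freqs[labels[i]], freqs[labels[j]]
            ok = ~(np.isnan(px) | np.isnan(py))
            x, y = px[ok], py[ok]
            num = float((2.0 * (x - y) ** 2).sum())
            den = float((2.0 * (1.0 - x * y - (1.0 - x) * (1.0 - y))).sum())
            theta = num / den if den > 0 else 0.0
            if linearized:
                theta = -np.log(max(1.0 - theta, 1e-300))
            d[i, j] = d[j, i] = theta
    return DistanceMatrix(labels=list(labels), d=d, level="breed")


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------


def neighbor_joining(D: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Standard NJ agglomeration; deterministic (first minimal Q pair in label order).

    Returns an unrooted tree as a trifurcating-rooted :class:`skbio.TreeNode`.
    Negative branch-length estimates are clamped to zero with a warning
    unless ``clamp_negative`` is False.
    """
    n = len(D.labels)
    if n < 3:
        raise GaldivError("neighbor-joining needs at least 3 labels")
    if np.isnan(D.d).any():
        raise GaldivError("distance matrix contains undefined entries")
    d = D.d.astype(float).copy()
    nodes = [TreeNode(name=label) for label in D.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # first minimal pair in (row-major) label order
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        parent.append(ci)
        parent.append(cj)
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[x] for x in keep] + [parent]

    # final three nodes joined at an unrooted trifurcation
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode()
    for node, length in ((a, la), (b, lb), (c, lc)):
        node.length = float(length)
        root.append(node)

    negatives = [node for node in root.traverse(include_self=False) if node.length < 0]
    if negatives:
        if clamp_negative:
            warnings.warn(
                f"{len(negatives)} negative NJ branch length(s) clamped to 0",
                stacklevel=2,
            )
            for node in negatives:
                node.length = 0.0
    return root


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEEDS_QUOTING = re.compile(r"[\s()\[\]{}:;,='\"]")


def _quote_label(label: str) -> str:
    if label and not _NEEDS_QUOTING.search(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_length(length) -> str:
    if length is None:
        return ""
    return f":{float(length):.6g}"


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick, branch lengths at 6 significant digits.

    Labels containing Newick metacharacters are single-quoted (with ''
    escaping), so a round-trip parse recovers them verbatim.
    """

    def render(node: TreeNode) -> str:
        if node.is_tip():
            return _quote_label(node.name or "") + _format_length(node.length)
        inner = ",".join(render(child) for child in node.children)
        name = _quote_label(node.name) if node.name else ""
        return f"({inner}){name}{_format_length(node.length)}"

    return render(tree) + ";"
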