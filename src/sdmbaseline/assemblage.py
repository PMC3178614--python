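"""Survey assemblage comparison: Bray-Curtis distances, Mantel tests,
richness summaries.

Two surveys of the same sites are compared by computing site-by-site
Bray-Curtis dissimilarities within each survey and testing, with a Mantel
permutation test, whether the two distance structures are correlated
(i.e., whether the spatial organization of the assemblage persisted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AssemblageMatrix",
    "DistanceMatrix",
    "MantelResult",
    "bray_curtis",
    "mantel_test",
    "richness_summary",
]


@dataclass
class AssemblageMatrix:
    """Sites x species non-negative abundance counts."""

    counts: pd.DataFrame  # index = site ids, columns = species ids
    label: str = "survey"

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def sites(self) -> list:
        return list(self.counts.index)

    @property
    def species(self) -> list:
        return list(self.counts.columns)

    @classmethod
    def from_csv(cls, path, label: str = "survey") -> "AssemblageMatrix":
        return cls(pd.read_csv(path, index_col=0), label=label)


@dataclass
class DistanceMatrix:
    """Symmetric site dissimilarities with zero diagonal, entries in [0,1]."""

    values: np.ndarray
    site_ids: list
    double_zero_pairs: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def bray_curtis(m: AssemblageMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all site pairs.

    d(i, j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk).  A pair of
    all-zero sites is defined as distance 0 (identical emptiness) and
    flagged in ``double_zero_pairs``.
    """
    x = m.counts.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two sites for a distance matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 handled below
        d = squareform(pdist(x, metric="braycurtis"))
    empty = ~x.any(axis=1)
    pairs = []
    if empty.any():
        idx = np.flatnonzero(empty)
        for a in idx:
            for b in idx:
                if a < b:
                    d[a, b] = d[b, a] = 0.0
                    pairs.append((m.sites[a], m.sites[b]))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, site_ids=m.sites, double_zero_pairs=pairs)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int
    tail: str


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    tail: str = "greater",
) -> MantelResult:
    """Mantel permutation test of correlation between two distance matrices.

    r is the Pearson correlation of corresponding lower-triangle entries;
    the null distribution is generated by jointly permuting the rows and
    columns of ``d2``.  p = (1 + #{r_perm >= r_obs}) / (1 + n_perm) for
    ``tail="greater"``; the two-sided tail counts |r_perm| >= |r_obs|.
    """
    if d1.site_ids != d2.site_ids:
        raise ValueError("distance matrices must index the same sites in the same order")
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    n = d1.n_sites
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    v2 = d2.values[iu]
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("constant distance matrix; Mantel r undefined")

    def _corr(a, b):
        a = a - a.mean(axis=-1, keepdims=True)
        b = b - b.mean(axis=-1, keepdims=True)
        return (a * b).sum(axis=-1) / np.sqrt((a * a).sum(axis=-1) * (b * b).sum(axis=-1))

    r_obs = float(_corr(v1, v2))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    # gather permuted lower triangles of d2 in one shot
    perm_vals = d2.values[perms[:, iu[0]], perms[:, iu[1]]]
    r_perm = _corr(np.broadcast_to(v1, perm_vals.shape), perm_vals)
    if tail == "greater":
        exceed = int((r_perm >= r_obs).sum())
    else:
        exceed = int((np.abs(r_perm) >= abs(r_obs)).sum())
    p = (1 + exceed) / (1 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_permutations=n_perm,
                        seed=seed, tail=tail)


def richness_summary(matrices: Mapping[str, AssemblageMatrix]) -> dict[str, pd.DataFrame]:
    """Per-site richness, per-survey totals, relative abundances, and
    shared-species counts between each pair of surveys."""
    site_rows, totals_rows, relab_frames = [], [], {}
    for label, m in matrices.items():
        x = m.counts
        rich = (x > 0).sum(axis=1)
        for site, r in rich.items():
            site_rows.append({"survey": label, "site": site,
                              "richness": int(r),
                              "n_individuals": int(x.loc[site].sum())})
        totals_rows.append({"survey": label,
                            "n_species": int((x.sum(axis=0) > 0).sum()),
                            "n_individuals": int(x.to_numpy().sum())})
        tot = x.to_numpy().sum()
        relab_frames[label] = (x.sum(axis=0) / tot) if tot else x.sum(axis=0)
    shared_rows = []
    labels = list(matrices)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            sa = set(np.asarray(matrices[a].species)[
                matrices[a].counts.sum(axis=0).to_numpy() > 0])
            sb = set(np.asarray(matrices[b].species)[
                matrices[b].counts.sum(axis=0).to_numpy() > 0])
            shared_rows.append({"survey_a": a, "survey_b": b,
                                "shared": len(sa & sb),
                                "union": len(sa | sb)})
    return {
        "per_site": pd.DataFrame(site_rows),
        "per_survey": pd.DataFrame(totals_rows),
        "relative_abundance": pd.DataFrame(relab_frames).fillna(0.0),
        "shared_species": pd.DataFrame(shared_rows),
    }
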