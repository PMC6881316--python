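"""Reference-spectrum clustering and the commercial-label audit.

Consensus spectra are compared by correlation distance (d = 1 - Pearson r
over the union of their binned peaks), clustered by average linkage
(UPGMA), and cut at the number of clusters maximizing the mean silhouette
width. The audit compares how each specimen was marketed with its molecular
species assignment under an explicit synonymy/species-complex policy, since
a marketed trade name may be an accepted synonym (or an accepted complex
member) rather than a mislabel.
"""
from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .msp import bin_peaklists
from .types import MSP, SpecimenRecord

__all__ = [
    "Dendrogram",
    "SynonymyPolicy",
    "msp_distance",
    "distance_matrix",
    "linkage_average",
    "cut_by_silhouette",
    "concordance",
    "misidentification_report",
]


@dataclass
class Dendrogram:
    """Average-linkage merge tree: a scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = self.linkage.shape[0] + 1
        if self.linkage.ndim != 2 or self.linkage.shape[1] != 4:
            raise ValueError("linkage must be an (n-1) x 4 matrix")
        if self.labels and len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} leaves")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return self.linkage.shape[0] + 1


def msp_distance(a: MSP, b: MSP, tol_ppm: float = 2000.0) -> float:
    """Correlation distance between two consensus spectra.

    The peaks of both spectra are binned together (same single-linkage ppm
    binning as consensus building); each spectrum contributes its intensity
    to the bins it occupies and 0 elsewhere; d = 1 - Pearson r of the two
    vectors, in [0, 2]. If either vector is constant the correlation is
    undefined and d = 1 (uninformative).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot compare an empty consensus spectrum")
    bins = bin_peaklists([a.as_peaklist(), b.as_peaklist()], tol_ppm)
    va = np.zeros(len(bins))
    vb = np.zeros(len(bins))
    for i, bn in enumerate(bins):
        for src, _, inten in bn.members:
            if src == 0:
                va[i] = inten
            else:
                vb[i] = inten
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return 1.0
    r = float(np.corrcoef(va, vb)[0, 1])
    return float(1.0 - r)


def distance_matrix(library: Sequence[MSP], tol_ppm: float = 2000.0):
    """Symmetric zero-diagonal correlation-distance matrix over a library.

    Returns ``(matrix, labels)``.
    """
    n = len(library)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = msp_distance(library[i], library[j], tol_ppm)
    return dm, [m.label for m in library]


def linkage_average(dm: np.ndarray, labels: Sequence[str] = ()) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix."""
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(np.isnan(dm)):
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(dm)) > 1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    z = linkage(squareform(dm, checks=False), method="average")
    return Dendrogram(linkage=z, labels=list(labels))


def cut_by_silhouette(
    dendrogram: Dendrogram,
    dm: np.ndarray,
    k_range: Sequence[int] = range(2, 13),
):
    """Choose the flat cut maximizing mean silhouette width.

    For each candidate k the dendrogram is cut into k flat clusters and the
    mean silhouette width is computed on the distance matrix; the best k
    wins, ties going to the smaller k. Returns ``(k, labels)`` with labels
    as a 1-based integer array over the leaves.

    Degenerate input (all leaves effectively identical) yields k = 2 with a
    warning; the silhouette is 0 there.
    """
    n = dendrogram.n_leaves
    if n < 3:
        raise ValueError("need at least 3 leaves to choose a cut")
    dm = np.asarray(dm, dtype=float)

    best_k, best_labels, best_score = None, None, -np.inf
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        labels = fcluster(dendrogram.linkage, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            score = silhouette_score(dm, labels, metric="precomputed")
        if not np.isfinite(score):
            score = 0.0
        if score > best_score:
            best_k, best_labels, best_score = k, labels, score
    if best_labels is None or best_score <= 0 and not np.any(dm > 1e-12):
        warnings.warn("degenerate distance matrix (all leaves identical); k = 2")
        return 2, fcluster(dendrogram.linkage, t=2, criterion="maxclust")
    return best_k, best_labels


def concordance(labels: Mapping[str, int], truth: Mapping[str, str]):
    """Adjusted Rand index and per-cluster purity of a flat clustering
    against a reference partition (e.g. molecular species assignments).

    Returns ``(ari, purity)`` with purity a dict cluster -> fraction of its
    members carrying the cluster's majority truth label.
    """
    if set(labels) != set(truth):
        raise ValueError("clustering and truth cover different leaf sets")
    keys = sorted(labels)
    pred = [labels[k] for k in keys]
    true = [truth[k] for k in keys]
    ari = float(adjusted_rand_score(true, pred))
    purity: dict = {}
    for cl in sorted(set(pred)):
        members = [t for p, t in zip(pred, true) if p == cl]
        counts = pd.Series(members).value_counts()
        purity[cl] = float(counts.iloc[0] / len(members))
    return ari, purity


# ------------------------------------------------------------------ audit

@dataclass
class SynonymyPolicy:
    """How trade names relate to accepted species names.

    ``synonyms`` maps a name to its canonical binomial (applied always,
    e.g. a junior synonym to the accepted name). ``complexes`` maps a
    nominal species to the members of its species complex and to the subset
    of members whose sale under the nominal name is accepted. Under the
    ``lenient`` policy an assignment inside the accepted set of the marketed
    nominal species is not a mislabel; under ``strict`` only an exact
    canonical match passes.
    """

    synonyms: Mapping[str, str] = field(default_factory=dict)
    complexes: Mapping[str, Mapping[str, Sequence[str]]] = field(default_factory=dict)
    mode: str = "lenient"

    def __post_init__(self) -> None:
        if self.mode not in ("lenient", "strict"):
            raise ValueError(f"unknown policy mode {self.mode!r}")
        for name in self.synonyms:
            seen = {name}
            cur = name
            while cur in self.synonyms:
                cur = self.synonyms[cur]
                if cur in seen:
                    raise ValueError(f"synonym cycle involving {name!r}")
                seen.add(cur)

    def canonical(self, name: str) -> str:
        cur = name
        while cur in self.synonyms:
            cur = self.synonyms[cur]
        return cur

    def is_misidentified(self, marketed: str, assigned: str) -> bool:
        cm = self.canonical(marketed)
        ca = self.canonical(assigned)
        if cm == ca:
            return False
        if self.mode == "lenient" and cm in self.complexes:
            accepted = set(self.complexes[cm].get("accepted", ()))
            if ca in accepted:
                return False
        return True

    @classmethod
    def from_toml(cls, path, mode: Optional[str] = None) -> "SynonymyPolicy":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        return cls(
            synonyms=doc.get("synonyms", {}),
            complexes=doc.get("complexes", {}),
            mode=mode or doc.get("mode", "lenient"),
        )

    @classmethod
    def default(cls, mode: Optional[str] = None) -> "SynonymyPolicy":
        """The packaged policy for the truffle market fixture."""
        ref = resources.files("spectratype.data") / "default_policy.toml"
        with resources.as_file(ref) as path:
            return cls.from_toml(path, mode=mode)


def _percent(n: int, total: int) -> int:
    if total == 0:
        return 0
    return int(100.0 * n / total + 0.5)


def misidentification_report(
    records: Sequence[SpecimenRecord],
    policy: SynonymyPolicy,
) -> pd.DataFrame:
    """Audit marketed names against molecular assignments.

    One row per specimen with the canonicalized names and the verdict; the
    frame carries ``attrs``: ``n_misidentified``, ``percent`` (integer-
    rounded), and ``by_marketed`` — a per-trade-name breakdown frame with
    n, n_misidentified and percent columns.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "specimen_id": rec.specimen_id,
                "marketed_species": rec.marketed_species,
                "assigned_species": rec.assigned_species,
                "canonical_marketed": policy.canonical(rec.marketed_species),
                "canonical_assigned": policy.canonical(rec.assigned_species),
                "misidentified": policy.is_misidentified(
                    rec.marketed_species, rec.assigned_species
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["specimen_id", "marketed_species", "assigned_species",
                 "canonical_marketed", "canonical_assigned", "misidentified"],
    )
    n_mis = int(df["misidentified"].sum()) if len(df) else 0
    df.attrs["n_misidentified"] = n_mis
    df.attrs["n_total"] = len(df)
    df.attrs["percent"] = _percent(n_mis, len(df))
    if len(df):
        grp = (
            df.groupby("marketed_species", sort=True)["misidentified"]
            .agg(n="count", n_misidentified="sum")
            .reset_index()
        )
        grp["n_misidentified"] = grp["n_misidentified"].astype(int)
        grp["percent"] = [
            _percent(m, n) for m, n in zip(grp["n_misidentified"], grp["n"])
        ]
    else:
        grp = pd.DataFrame(
            columns=["marketed_species", "n", "n_misidentified", "percent"]
        )
    df.attrs["by_marketed"] = grp
    return df
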