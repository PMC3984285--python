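"""Supervised admixture estimation and ancestry-based subpopulation assignment.

Each subject's genome is modelled as a mixture of six fixed ancestral
populations (African, European, Native American, East Asian, Central Asian,
Oceanic) with known alt-allele frequencies at a panel of informative SNPs.
Per-subject mixing coefficients q (non-negative, summing to 1) are estimated by
maximising the binomial log-likelihood

    L(q) = sum_l [ x_l log(sum_k q_k f_kl) + (2 - x_l) log(sum_k q_k (1 - f_kl)) ]

over the simplex with an EM algorithm from a uniform start (x_l = alt dosage).
Subjects are then partitioned into labelled subpopulations by explicit
thresholds on the estimated coefficients; clusters below a minimum size are
aggregated into an "Other" group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

POPULATIONS = (
    "African",
    "European",
    "NativeAmerican",
    "EastAsian",
    "CentralAsian",
    "Oceanic",
)
POP_INDEX = {p: i for i, p in enumerate(POPULATIONS)}

SUBPOP_LABELS = (
    "African",
    "African-European",
    "CentralAsian",
    "EastAsian",
    "European",
    "Hispanic",
    "Other",
)

PANEL_FREQ_COLUMNS = [f"f_{p}" for p in POPULATIONS]

_EPS = 1e-6


@dataclass
class AncestralPanel:
    """Reference panel: marker keys plus alt-allele frequency per ancestral population."""

    markers: pd.DataFrame  # chrom, pos, ref, alt
    freqs: np.ndarray  # (n_markers, 6) in [0, 1]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.markers), len(POPULATIONS)):
            raise ValueError(
                f"freqs shape {self.freqs.shape} != ({len(self.markers)}, {len(POPULATIONS)})"
            )
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("panel frequencies must lie in [0, 1]")
        keys = list(zip(self.markers.chrom, self.markers.pos, self.markers.ref, self.markers.alt))
        if len(set(keys)) != len(keys):
            raise ValueError("panel marker keys must be unique")

    @classmethod
    def from_tsv(cls, path) -> "AncestralPanel":
        df = pd.read_csv(path, sep="\t")
        missing = {"chrom", "pos", "ref", "alt", *PANEL_FREQ_COLUMNS} - set(df.columns)
        if missing:
            raise ValueError(f"panel TSV missing columns {sorted(missing)}")
        return cls(df[["chrom", "pos", "ref", "alt"]], df[PANEL_FREQ_COLUMNS].to_numpy())

    def to_tsv(self, path) -> None:
        out = self.markers.copy()
        for j, c in enumerate(PANEL_FREQ_COLUMNS):
            out[c] = self.freqs[:, j]
        out.to_csv(path, sep="\t", index=False)


@dataclass
class AdmixtureResult:
    subjects: list[str]
    q: np.ndarray  # (n_subjects, 6)
    log_likelihood: np.ndarray
    n_iter: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.q, columns=list(POPULATIONS))
        df.insert(0, "subject", self.subjects)
        df["log_likelihood"] = self.log_likelihood
        return df


def estimate_admixture(
    dosage: np.ndarray,
    panel: AncestralPanel | np.ndarray,
    subjects: list[str] | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
    min_markers: int = 100,
    return_trajectory: bool = False,
) -> AdmixtureResult:
    """Estimate per-subject admixture coefficients by EM against fixed panel
    frequencies (supervised mode).

    ``dosage`` is (n_subjects, n_markers) with alt dosage 0/1/2 and -1 for
    missing.  The EM update multiplies each coefficient by its expected share
    of allele ancestries; the log-likelihood is non-decreasing and iteration
    stops when its per-subject change falls below ``tol`` or at ``max_iter``.
    Panel frequencies of exactly 0 or 1 are clipped to keep the likelihood
    finite.
    """
    dosage = np.asarray(dosage)
    n, L = dosage.shape
    freqs = panel.freqs if isinstance(panel, AncestralPanel) else np.asarray(panel, dtype=float)
    if L != len(freqs):
        raise ValueError(f"dosage has {L} markers, panel has {len(freqs)}")
    called = dosage >= 0
    n_called = called.sum(axis=1)
    if (n_called < min_markers).any():
        bad = int((n_called < min_markers).sum())
        raise ValueError(
            f"{bad} subject(s) have fewer than {min_markers} called panel markers"
        )
    F = np.clip(freqs.T.astype(float), _EPS, 1.0 - _EPS)  # (K, L)
    K = F.shape[0]
    X = np.where(called, dosage, 0).astype(float)
    X2 = np.where(called, 2.0 - dosage, 0.0)

    Q = np.full((n, K), 1.0 / K)
    ll_prev = np.full(n, -np.inf)
    n_iter = np.zeros(n, dtype=int)
    active = np.ones(n, dtype=bool)
    ll = ll_prev.copy()
    trajectory: list[np.ndarray] = []
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        Xa, X2a, Qa = X[idx], X2[idx], Q[idx]
        P = Qa @ F  # (n_active, L) prob of alt allele
        Pc = np.clip(P, 1e-300, 1.0)
        Qc = np.clip(1.0 - P, 1e-300, 1.0)
        lla = np.einsum("nl,nl->n", Xa, np.log(Pc)) + np.einsum(
            "nl,nl->n", X2a, np.log(Qc)
        )
        ll[idx] = lla
        if return_trajectory:
            trajectory.append(ll.copy())
        done = np.abs(lla - ll_prev[idx]) < tol
        n_iter[idx] = it
        ll_prev[idx] = lla
        active[idx[done]] = False
        if not active.any():
            break
        # EM multiplicative update on the still-active subjects
        keep = ~done
        A = Xa[keep] / Pc[keep]
        B = X2a[keep] / Qc[keep]
        num = Qa[keep] * (A @ F.T + B @ (1.0 - F.T))
        Q[idx[keep]] = num / num.sum(axis=1, keepdims=True)
    Q = np.clip(Q, 0.0, 1.0)
    Q /= Q.sum(axis=1, keepdims=True)
    if subjects is None:
        subjects = [f"S{i:04d}" for i in range(n)]
    result = AdmixtureResult(subjects=list(subjects), q=Q, log_likelihood=ll, n_iter=n_iter)
    if return_trajectory:
        result.trajectory = np.array(trajectory)  # type: ignore[attr-defined]
    return result


@dataclass(frozen=True)
class ClusterConfig:
    """Threshold rules reconstructing the reported subpopulation boundaries.

    dominant_min: minimum largest coefficient to join a single-ancestry cluster
    (the reported boundaries are breakpoints at 78-83%; one configurable
    threshold is used for all four).
    afr_eur_sum_min / afr_range: African-European cluster needs African+European
    covering at least 95% of ancestry with African inside [0.13, 0.75].
    hispanic: any Native American component at least na_min together with a
    European component and at most 50% African.
    """

    dominant_min: float = 0.78
    afr_eur_sum_min: float = 0.95
    afr_range: tuple[float, float] = (0.13, 0.75)
    hispanic_na_min: float = 0.05
    hispanic_eur_min: float = 0.05
    hispanic_afr_max: float = 0.50
    min_cluster_size: int = 20

DOMINANT_LABELS = {
    "African": "African",
    "European": "European",
    "EastAsian": "EastAsian",
    "CentralAsian": "CentralAsian",
    "NativeAmerican": "NativeAmerican",
    "Oceanic": "Oceanic",
}


def cluster_subjects(
    q: np.ndarray,
    config: ClusterConfig = ClusterConfig(),
    method: str = "thresholds",
    n_clusters: int = 7,
    seed: int | None = None,
) -> np.ndarray:
    """Assign each subject a raw cluster label from admixture coefficients.

    The default is the explicit threshold rule; ``method='kmeans'`` offers a
    generic alternative for sensitivity analysis (labels are then the dominant
    mean ancestry of each k-means cluster, which may merge or split the
    threshold-rule groups).  Clusters smaller than ``min_cluster_size`` and
    unassigned subjects are merged into "Other" by :func:`label_clusters` /
    :func:`assign_subpopulations`.
    """
    q = np.asarray(q, dtype=float)
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(q)
        labels = np.empty(len(q), dtype=object)
        for c in range(n_clusters):
            members = km.labels_ == c
            mean_q = q[members].mean(axis=0)
            labels[members] = POPULATIONS[int(np.argmax(mean_q))]
        return labels

    i_afr = POP_INDEX["African"]
    i_eur = POP_INDEX["European"]
    i_na = POP_INDEX["NativeAmerican"]
    labels = np.full(len(q), "unassigned", dtype=object)
    dominant = q.argmax(axis=1)
    dom_ok = q.max(axis=1) >= config.dominant_min
    for k, pop in enumerate(POPULATIONS):
        labels[dom_ok & (dominant == k)] = DOMINANT_LABELS[pop]

    unas = labels == "unassigned"
    afr_eur = (
        unas
        & (q[:, i_afr] + q[:, i_eur] >= config.afr_eur_sum_min)
        & (q[:, i_afr] >= config.afr_range[0])
        & (q[:, i_afr] <= config.afr_range[1])
    )
    labels[afr_eur] = "African-European"

    unas = labels == "unassigned"
    hispanic = (
        unas
        & (q[:, i_na] >= config.hispanic_na_min)
        & (q[:, i_eur] >= config.hispanic_eur_min)
        & (q[:, i_afr] <= config.hispanic_afr_max)
    )
    labels[hispanic] = "Hispanic"
    return labels


def label_clusters(
    labels: np.ndarray,
    birth_country: pd.DataFrame | None = None,
    country_region: dict[str, str] | None = None,
) -> np.ndarray:
    """Optionally relabel clusters by the majority birth region of their members.

    ``birth_country`` maps subject index order to a country; ``country_region``
    maps countries to region labels.  United States-born subjects are excluded
    from the vote.  Ties or empty votes keep the ancestry-rule label with a
    warning.  Without a table, the ancestry-rule labels stand.
    """
    if birth_country is None:
        return labels
    if country_region is None:
        country_region = {}
    out = labels.copy()
    countries = birth_country["country"].to_numpy()
    for lab in pd.unique(labels):
        if lab in ("unassigned", "Other"):
            continue
        members = labels == lab
        votes = pd.Series(
            [
                country_region.get(c, c)
                for c in countries[members]
                if c != "United States"
            ]
        )
        if votes.empty:
            warnings.warn(f"cluster {lab}: all members US-born; keeping ancestry label")
            continue
        counts = votes.value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            warnings.warn(f"cluster {lab}: tied region vote; keeping ancestry label")
            continue
        out[members] = counts.index[0]
    return out


def assign_subpopulations(
    subjects: list[str],
    labels: np.ndarray,
    min_cluster_size: int = 20,
) -> pd.DataFrame:
    """Merge unassigned subjects and undersized clusters into "Other".

    Returns a subject -> subpopulation table; the labels partition the cohort
    and every non-Other group has at least ``min_cluster_size`` members.
    """
    labels = np.asarray(labels, dtype=object).copy()
    labels[labels == "unassigned"] = "Other"
    sizes = pd.Series(labels).value_counts()
    for lab, size in sizes.items():
        if lab != "Other" and size < min_cluster_size:
            labels[labels == lab] = "Other"
    return pd.DataFrame({"subject": subjects, "subpopulation": labels})
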