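"""Patient stratification and per-variant cohort allele statistics.

Patients are split into high-toxicity (HT) and low-toxicity (LT) cohorts by
unsupervised k-means (k = 2) on three blood-count phenotypes measured at
nadir: neutropenia, leukopenia and thrombocytopenia. Lower counts mean worse
myelosuppression, so the cluster with the lower mean standardized counts is
labeled HT.

Per variant, the alt-allele count AC and frequency AF are computed within
each cohort and contrasted through normalized absolute differences

    ACdiff = |AC.LT - AC.HT| / (AC.LT + AC.HT)
    AFdiff = |AF.LT - AF.HT| / (AF.LT + AF.HT)

A variant is a *candidate* when AFdiff > ACEthr, ACdiff > ACEthr and
|AC.LT - AC.HT| > 1 (ACEthr defaults to 0.25); everything else is "rest".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .errors import DegenerateInputError, ParameterError, ValidationError
from .io_formats import GenotypeMatrix, PipelineConfig

logger = logging.getLogger(__name__)

HT = "HT"
LT = "LT"

#: columns of the frame returned by :func:`cohort_allele_stats`
STATS_COLUMNS = (
    "variant",
    "ac_lt",
    "ac_ht",
    "af_lt",
    "af_ht",
    "ac_diff",
    "af_diff",
    "ac_abs_diff",
    "n_lt",
    "n_ht",
    "is_candidate",
)


@dataclass
class CohortAssignment:
    """HT/LT label per patient plus the k-means centroids (original units)."""

    labels: dict[str, str]
    centroids: pd.DataFrame  # index HT/LT, columns = phenotype names

    def patients(self, label: str) -> list[str]:
        return [p for p, lab in self.labels.items() if lab == label]

    @property
    def sizes(self) -> tuple[int, int]:
        """(n_HT, n_LT)."""
        return len(self.patients(HT)), len(self.patients(LT))


def cluster_patients(
    phenotypes: pd.DataFrame,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> CohortAssignment:
    """Split patients into HT/LT cohorts by seeded k-means (k = 2).

    Features are standardized to zero mean / unit variance; k-means runs 10
    seeded restarts. The cluster with the lower mean of standardized counts
    is HT (lower nadir blood counts = more severe toxicity). Rows containing
    missing values are dropped with a logged count.
    """
    config = config or PipelineConfig()
    seed = config.rng_seed if seed is None else seed

    pheno = phenotypes.astype(float)
    complete = pheno.dropna()
    n_dropped = len(pheno) - len(complete)
    if n_dropped:
        logger.info("dropped %d patients with missing phenotype values", n_dropped)
    if len(complete) < 4:
        raise ParameterError("need at least 4 patients with complete phenotypes")
    if (complete.nunique() <= 1).all():
        raise DegenerateInputError(
            "all patients have identical blood counts; no meaningful split"
        )

    scaler = StandardScaler()
    X = scaler.fit_transform(complete.to_numpy())
    km = KMeans(n_clusters=config.k_clusters, n_init=10, random_state=seed)
    assignment = km.fit_predict(X)

    # the cluster with the lower mean standardized count is high-toxicity
    cluster_means = np.array(
        [X[assignment == k].mean() for k in range(config.k_clusters)]
    )
    ht_cluster = int(np.argmin(cluster_means))
    labels = {
        patient: (HT if cl == ht_cluster else LT)
        for patient, cl in zip(complete.index, assignment)
    }
    centroids_orig = scaler.inverse_transform(km.cluster_centers_)
    centroids = pd.DataFrame(
        centroids_orig[[ht_cluster, 1 - ht_cluster]],
        index=[HT, LT],
        columns=complete.columns,
    )
    return CohortAssignment(labels, centroids)


def _normalized_abs_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|a - b| / (a + b), defined as 0 where a + b == 0."""
    total = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(a - b) / total
    out[total == 0] = 0.0
    return out


def cohort_allele_stats(
    genotypes: GenotypeMatrix, cohorts: CohortAssignment
) -> pd.DataFrame:
    """Per-variant AC/AF per cohort and the normalized differences.

    Missing genotypes are excluded from both the AC numerator and the AF
    denominator (AF = AC / (2 x non-missing patients in the cohort)). Returns
    one row per variant with :data:`STATS_COLUMNS`; ``is_candidate`` is
    initialized to False (see :func:`filter_candidates`).
    """
    unlabeled = [p for p in genotypes.patients if p not in cohorts.labels]
    if unlabeled:
        raise ValidationError(f"patients without a cohort label: {unlabeled[:5]}")

    gt = genotypes.genotypes
    label_arr = np.array([cohorts.labels[p] for p in genotypes.patients])
    out = {}
    for name, cohort in (("lt", LT), ("ht", HT)):
        sub = gt[:, label_arr == cohort]
        observed = sub != GenotypeMatrix.MISSING
        ac = np.where(observed, sub, 0).sum(axis=1)
        n_obs = observed.sum(axis=1)
        denom = 2 * n_obs
        with np.errstate(divide="ignore", invalid="ignore"):
            af = np.where(denom > 0, ac / np.maximum(denom, 1), 0.0)
        out[f"ac_{name}"] = ac.astype(int)
        out[f"af_{name}"] = af
        out[f"n_{name}"] = n_obs.astype(int)

    df = pd.DataFrame(
        {
            "variant": genotypes.variant_ids,
            "ac_lt": out["ac_lt"],
            "ac_ht": out["ac_ht"],
            "af_lt": out["af_lt"],
            "af_ht": out["af_ht"],
        }
    )
    df["ac_diff"] = _normalized_abs_diff(
        df["ac_lt"].to_numpy(float), df["ac_ht"].to_numpy(float)
    )
    df["af_diff"] = _normalized_abs_diff(
        df["af_lt"].to_numpy(), df["af_ht"].to_numpy()
    )
    df["ac_abs_diff"] = (df["ac_lt"] - df["ac_ht"]).abs()
    df["n_lt"] = out["n_lt"]
    df["n_ht"] = out["n_ht"]
    df["is_candidate"] = False
    return df[list(STATS_COLUMNS)]


def filter_candidates(
    stats: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Set ``is_candidate`` on the allele-stats frame.

    Candidate <=> AFdiff > ace_thr AND ACdiff > ace_thr AND |AC.LT - AC.HT| > 1.
    With ``config.require_two_carriers`` the additional textual criterion —
    the alt allele observed in at least two individuals overall — is applied
    on top (off by default).
    """
    config = config or PipelineConfig()
    df = stats.copy()
    candidate = (
        (df["af_diff"] > config.ace_thr)
        & (df["ac_diff"] > config.ace_thr)
        & (df["ac_abs_diff"] > 1)
    )
    if config.require_two_carriers:
        candidate &= (df["ac_lt"] + df["ac_ht"]) >= 2
    df["is_candidate"] = candidate
    return df
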