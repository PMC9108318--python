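"""Season classification from dissolved oxygen, and environmental PCA.

A month is labelled *hypoxia* when the minimum dissolved-oxygen value over
all of that month's samples (both water layers) falls strictly below a
threshold, 2 mg/L by default — a conventional hypoxia threshold for coastal
waters. All samples of such a month share the label, so that samples from
the same period are analysed as one unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

HYPOXIA_THRESHOLD_MG_L = 2.0

ENV_VARIABLES = ("dissolved_oxygen", "temperature", "salinity")

HYPOXIA = "hypoxia"
NORMOXIA = "normoxia"


@dataclass(frozen=True)
class SeasonLabeling:
    """month -> season label, derived from monthly minimum DO vs threshold."""

    labels: Mapping[int, str]
    threshold: float

    @property
    def hypoxia_months(self) -> list[int]:
        return sorted(m for m, lab in self.labels.items() if lab == HYPOXIA)

    @property
    def normoxia_months(self) -> list[int]:
        return sorted(m for m, lab in self.labels.items() if lab == NORMOXIA)

    def label_of(self, month: int) -> str:
        return self.labels[month]

    def sample_labels(self, metadata: pd.DataFrame) -> pd.Series:
        """Season label per sample, joined via the month column."""
        return metadata["month"].map(self.labels).rename("season")


def read_env_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read an environmental table with sample_id, dissolved_oxygen,
    temperature, salinity columns."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = ({"sample_id"} | set(ENV_VARIABLES)) - set(df.columns)
    if missing:
        raise ValueError(f"environment table missing columns: {sorted(missing)}")
    out = df[["sample_id", *ENV_VARIABLES]].copy()
    out["sample_id"] = out["sample_id"].astype(str)
    for v in ENV_VARIABLES:
        out[v] = out[v].astype(float)
    if out[list(ENV_VARIABLES)].isna().any().any():
        raise ValueError("missing environmental values; samples without complete environment must be excluded upstream")
    if (out["dissolved_oxygen"] < 0).any() or (out["salinity"] < 0).any():
        raise ValueError("negative dissolved oxygen or salinity")
    return out


def classify_seasons(
    env: pd.DataFrame,
    metadata: pd.DataFrame,
    threshold: float = HYPOXIA_THRESHOLD_MG_L,
) -> SeasonLabeling:
    """Label each month hypoxia/normoxia from its minimum dissolved oxygen.

    Parameters
    ----------
    env:
        Environmental table with ``sample_id`` and ``dissolved_oxygen``.
    metadata:
        Sample metadata providing the month of each sample.
    threshold:
        Hypoxia threshold in mg/L. A month is hypoxic iff its minimum DO
        is strictly below this value.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    merged = metadata[["sample_id", "month"]].merge(env[["sample_id", "dissolved_oxygen"]], on="sample_id")
    months_present = set(metadata["month"].unique())
    monthly_min = merged.groupby("month")["dissolved_oxygen"].min()
    missing = months_present - set(monthly_min.index)
    if missing:
        raise ValueError(f"months without any DO value: {sorted(missing)}")
    labels = {int(m): (HYPOXIA if v < threshold else NORMOXIA) for m, v in monthly_min.items()}
    return SeasonLabeling(labels=labels, threshold=threshold)


@dataclass
class PcaResult:
    """Principal components of the environmental variables.

    ``scores`` are sample coordinates, ``loadings`` the variable weights
    (columns of the rotation matrix), ``variance_fraction`` the fraction of
    total variance per component. Component signs follow the convention that
    each component's largest-magnitude loading is positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    standardized: bool = field(default=True)


def run_pca(env_matrix: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """PCA of a samples x variables matrix.

    With ``standardize=True`` (default) variables are centered and scaled to
    unit variance before the eigendecomposition — appropriate when variables
    carry incommensurable units (mg/L, °C, PSU).
    """
    X = env_matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than variables")
    if np.isnan(X).any():
        raise ValueError("missing values in environmental matrix")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            const = [env_matrix.columns[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant variable(s) cannot be standardized: {const}")
        X = X / sd
    pca = PCA(n_components=p)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # variables x components
    # deterministic sign: largest-|loading| entry positive in each component
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    comp_names = [f"PC{i + 1}" for i in range(p)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=env_matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=env_matrix.columns, columns=comp_names),
        variance_fraction=pca.explained_variance_ratio_.copy(),
        standardized=standardize,
    )
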