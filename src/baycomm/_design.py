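"""Model-matrix construction shared by PERMANOVA and the mixed models.

Factors are dummy-coded with a fixed, documented coding for the two study
factors (season: hypoxia=0/normoxia=1; layer: surface=0/bottom=1); other
factors get drop-first dummies in sorted level order. Continuous covariates
are centered before interactions are formed, so interaction columns are
decorrelated from the main-effect columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: fixed dummy coding for the study factors
FACTOR_CODING = {
    "season": {"hypoxia": 0.0, "normoxia": 1.0},
    "layer": {"surface": 0.0, "bottom": 1.0},
}


def term_columns(
    data: pd.DataFrame, term: str, center_covariates: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Columns of the model matrix contributed by one term.

    ``term`` is a variable name or a ':'-separated interaction. Returns the
    (n, k) column block and its column labels.
    """
    if ":" in term:
        parts = term.split(":")
        block, names = term_columns(data, parts[0], center_covariates)
        for part in parts[1:]:
            other, onames = term_columns(data, part, center_covariates)
            block = np.einsum("ni,nj->nij", block, other).reshape(len(data), -1)
            names = [f"{a}:{b}" for a in names for b in onames]
        return block, names
    if term not in data.columns:
        raise KeyError(f"term '{term}' not in design data")
    col = data[term]
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        values = col.astype(str)
        if term in FACTOR_CODING:
            coding = FACTOR_CODING[term]
            unknown = set(values.unique()) - set(coding)
            if unknown:
                raise ValueError(f"unknown level(s) {sorted(unknown)} for factor '{term}'")
            coded = values.map(coding).to_numpy(dtype=float)[:, None]
            level1 = max(coding, key=coding.get)
            return coded, [f"{term}[{level1}]"]
        levels = sorted(values.unique())
        if len(levels) < 2:
            raise ValueError(f"factor '{term}' has a single level")
        block = np.column_stack([(values == lv).to_numpy(float) for lv in levels[1:]])
        return block, [f"{term}[{lv}]" for lv in levels[1:]]
    x = col.to_numpy(dtype=float)
    if center_covariates:
        x = x - x.mean()
    return x[:, None], [term]


def build_design(
    data: pd.DataFrame, terms: list[str], center_covariates: bool = True
) -> tuple[np.ndarray, list[str], list[int]]:
    """Full model matrix with intercept.

    Returns (X, column names, per-term column counts); the intercept is the
    first column and is not counted in the per-term list.
    """
    blocks = [np.ones((len(data), 1))]
    names = ["intercept"]
    counts = []
    for term in terms:
        b, n = term_columns(data, term, center_covariates)
        blocks.append(b)
        names.extend(n)
        counts.append(b.shape[1])
    return np.hstack(blocks), names, counts
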