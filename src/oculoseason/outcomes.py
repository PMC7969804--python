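"""Outcome construction: PC-ImPACT and subtractive (baseline) normalization.

The six ImPACT composites point in different directions (higher verbal,
visual and visual-motor scores are better; lower reaction time, impulse
control and symptom scores are better).  Before principal-component
analysis the reciprocals of the latter three are taken so that larger
always means better, and each column is standardized because the
composites live on wildly different scales.  PC-ImPACT is the first
principal-component score, oriented so the verbal/visual/visual-motor
loadings are positive — higher PC-ImPACT means higher functional
neurocognitive performance.

Subtractive normalization subtracts each subject's first-session
(pre-season baseline) value from every later measurement, for features and
outcomes alike; baseline rows are flagged and excluded from model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COMPOSITES = ["verbal", "visual", "visual_motor", "reaction_time",
              "impulse_control", "symptom"]
RECIPROCAL_COMPOSITES = ("reaction_time", "impulse_control", "symptom")
COGNITIVE_COMPOSITES = ("verbal", "visual", "visual_motor")


@dataclass
class PCModel:
    """Fitted PCA of the (transformed, standardized) ImPACT composites."""

    columns: list
    loadings: np.ndarray  # (n_features, n_components), orthonormal columns
    variance_explained: np.ndarray  # fractions, non-increasing
    means: np.ndarray  # of the reciprocal-transformed columns
    sds: np.ndarray
    orientation: str = "cognitive-loadings-positive"
    reciprocal: bool = True

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Scores of new rows using the stored means/SDs (no refitting)."""
        vals = (_reciprocal_transform(table[self.columns]) if self.reciprocal
                else table[self.columns].astype(float)).to_numpy()
        z = (vals - self.means) / self.sds
        return z @ self.loadings

    def first_pc_scores(self, table: pd.DataFrame) -> np.ndarray:
        return self.transform(table)[:, 0]


def _reciprocal_transform(table: pd.DataFrame) -> pd.DataFrame:
    out = table.astype(float).copy()
    for col in RECIPROCAL_COMPOSITES:
        if col in out.columns:
            vals = out[col].to_numpy()
            if np.any(vals <= 0):
                raise ValueError(
                    f"composite {col!r} must be strictly positive for the reciprocal transform")
            out[col] = 1.0 / vals
    return out


def impact_pc(table: pd.DataFrame, drop_symptom: bool = False,
              reciprocal: bool = True) -> tuple[pd.Series, PCModel]:
    """PC-ImPACT scores and the fitted :class:`PCModel`.

    ``table`` must contain the six composite columns (``drop_symptom=True``
    removes the subjective symptom score from the computation).  Scores have
    zero mean on the fitted rows.  ``reciprocal=False`` skips the reciprocal
    transform — used when the input is already transformed (e.g. deltas of
    reciprocal-transformed scores, see :func:`impact_pc_sn`).
    """
    cols = [c for c in COMPOSITES if c in table.columns]
    missing = [c for c in COMPOSITES if c not in table.columns and not
               (drop_symptom and c == "symptom")]
    if missing:
        raise ValueError(f"missing composite columns: {missing}")
    if drop_symptom:
        cols = [c for c in cols if c != "symptom"]
    if len(table) < 2:
        raise ValueError("need at least 2 rows to fit principal components")
    z_raw = (_reciprocal_transform(table[cols]) if reciprocal
             else table[cols].astype(float)).to_numpy()
    means = z_raw.mean(axis=0)
    sds = z_raw.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("a composite column is constant; cannot standardize")
    z = (z_raw - means) / sds
    # eigendecomposition of the sample covariance via SVD of the centred data
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s**2
    var_frac = var / var.sum()
    loadings = vt.T
    # orientation: cognitive loadings positive on the first PC
    cog_idx = [cols.index(c) for c in COGNITIVE_COMPOSITES]
    if loadings[cog_idx, 0].sum() < 0:
        loadings[:, 0] = -loadings[:, 0]
    model = PCModel(columns=cols, loadings=loadings, variance_explained=var_frac,
                    means=means, sds=sds, reciprocal=reciprocal)
    scores = pd.Series(z @ loadings[:, 0], index=table.index, name="pc_impact")
    return scores, model


def impact_pc_sn(table: pd.DataFrame, subject_col: str = "subject_id",
                 session_col: str = "session", drop_symptom: bool = False,
                 ) -> tuple[pd.Series, PCModel, pd.DataFrame]:
    """Subtractive-normalized PC-ImPACT.

    Individual composite scores are reciprocal-transformed first (deltas of
    a reciprocal are meaningful; reciprocals of deltas are not), then each
    subject's baseline is subtracted, and the PCA is fitted on the
    non-baseline delta rows.  Returns the scores (indexed like the
    non-baseline rows), the fitted model and the full delta table.
    """
    cols = [c for c in COMPOSITES if not (drop_symptom and c == "symptom")]
    work = table[[subject_col, session_col]].copy()
    work[cols] = _reciprocal_transform(table[cols])
    deltas = subtractive_normalize(work, subject_col, session_col, value_cols=cols)
    fit_rows = deltas[~deltas["is_baseline"]]
    scores, model = impact_pc(fit_rows, drop_symptom=drop_symptom, reciprocal=False)
    return scores, model, deltas


def subtractive_normalize(table: pd.DataFrame, subject_col: str = "subject_id",
                          session_col: str = "session",
                          value_cols: list | None = None) -> pd.DataFrame:
    """Subtract each subject's first-session value from every row.

    Returns a copy with the value columns replaced by deltas and an added
    boolean ``is_baseline`` column; baseline rows (all-zero deltas) are only
    used for normalization and must be excluded from model fitting, so the
    number of rows eligible for a subtractive-normalized fit is
    ``len(table) - n_subjects``.
    """
    if value_cols is None:
        value_cols = [c for c in table.columns
                      if c not in (subject_col, session_col)
                      and pd.api.types.is_numeric_dtype(table[c])]
    base_session = table[session_col].min()
    out = table.copy()
    baseline = table[table[session_col] == base_session].set_index(subject_col)
    for sid in table[subject_col].unique():
        if sid not in baseline.index:
            raise ValueError(f"subject {sid!r} has no baseline (session {base_session}) record")
    base_vals = baseline[value_cols].reindex(out[subject_col]).to_numpy()
    out[value_cols] = out[value_cols].to_numpy(dtype=float) - base_vals
    out["is_baseline"] = (table[session_col] == base_session).to_numpy()
    return out


def changes_summary(delta_table: pd.DataFrame, subject_col: str = "subject_id",
                    session_col: str = "session") -> pd.DataFrame:
    """Per-session mean and standard error of each normalized outcome."""
    value_cols = [c for c in delta_table.columns
                  if c not in (subject_col, session_col, "is_baseline")
                  and pd.api.types.is_numeric_dtype(delta_table[c])]
    rows = []
    for session, grp in delta_table.groupby(session_col):
        for col in value_cols:
            v = grp[col].dropna().to_numpy()
            if v.size == 0:
                continue
            se = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
            rows.append(dict(session=session, outcome=col, mean=float(np.mean(v)),
                             se=se, n=int(v.size)))
    return pd.DataFrame(rows)
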