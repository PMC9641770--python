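"""Per-sample transcription factor activity (TFA) estimation.

A TF's expression level need not reflect its regulatory activity (which may
be driven post-translationally), so activities are estimated from the
expression of its target genes instead: with a genes x TFs binary incidence
matrix C (targets defined by promoter binding sites), per-sample activities a
solve the ridge least-squares problem ``min ||e - C a||^2 + ridge ||a||^2`` on
standardised expression. The estimated activity columns can then replace the
TF expression columns before network inference.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import OmicsDataset

logger = logging.getLogger(__name__)


def estimate_tfa(
    expression: pd.DataFrame,
    incidence: pd.DataFrame,
    ridge: float = 1e-3,
) -> pd.DataFrame:
    """Estimate samples x TFs activities by ridge regression.

    ``expression`` is samples x genes; ``incidence`` is genes x TFs with 1
    where the gene is a target of the TF. Genes absent from the expression
    are dropped; TFs left without any target are dropped with a warning.
    """
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    genes = [g for g in incidence.index if g in expression.columns]
    if not genes:
        raise ValueError("no overlap between incidence genes and expression columns")
    C = incidence.loc[genes].to_numpy(dtype=float)
    keep = C.sum(axis=0) > 0
    dropped = [tf for tf, k in zip(incidence.columns, keep) if not k]
    if dropped:
        logger.warning("dropping TFs without targets: %s", dropped)
    C = C[:, keep]
    tfs = [tf for tf, k in zip(incidence.columns, keep) if k]
    if not tfs:
        raise ValueError("no TF has any target in the expression data")

    e = expression[genes].to_numpy(dtype=float)
    mu = e.mean(axis=0)
    sd = e.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    ez = (e - mu) / sd

    k = C.shape[1]
    # a = (C'C + ridge I)^{-1} C' e  per sample (shared solve across samples)
    gram = C.T @ C + ridge * np.eye(k)
    acts = np.linalg.solve(gram, C.T @ ez.T).T
    return pd.DataFrame(acts, index=expression.index, columns=tfs)


def substitute_tfa(
    data: OmicsDataset, tfa: pd.DataFrame, tfs: set[str]
) -> OmicsDataset:
    """Replace TF expression columns by activity estimates, in place order.

    ``tfs`` must be a subset of the data columns and of the TFA columns;
    samples must align. All other columns are untouched.
    """
    missing = tfs - set(data.values.columns)
    if missing:
        raise KeyError(f"TFs not in data columns: {sorted(missing)}")
    missing_tfa = tfs - set(tfa.columns)
    if missing_tfa:
        raise KeyError(f"TFs without activity estimates: {sorted(missing_tfa)}")
    if len(tfa) != data.n_samples or not (tfa.index == data.values.index).all():
        raise ValueError("sample index mismatch between data and TFA estimates")
    out = data.copy()
    for tf in tfs:
        out.values[tf] = tfa[tf].to_numpy()
    return out
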