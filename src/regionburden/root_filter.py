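"""Identify ancestor ("root") variants shared across tumor islets.

A root mutation predates clonal divergence: it is carried by essentially all
microdissected tumor islets (presence fraction >= 90% by default) and, when a
matched normal is available, absent from it.  Variant identity is
(chrom, pos, ref, alt); zygosity is ignored because islet calls are sparse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import VARIANT_KEY, distinct_variants

_FRACTION_EPS = 1e-12  # guards binary representation of exact fractions


@dataclass(frozen=True)
class AncestorCallConfig:
    islet_presence_threshold: float = 0.90
    require_absent_in_normal: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.islet_presence_threshold <= 1):
            raise ValueError("islet_presence_threshold must be in (0, 1]")


def presence_matrix(islet_tables: list[pd.DataFrame], names: list[str] | None = None) -> pd.DataFrame:
    """Boolean variants x islets matrix.

    Row sums are per-variant carrier counts; column sums are per-islet
    variant counts.  Rows are indexed by (chrom, pos, ref, alt).
    """
    if len(islet_tables) == 0:
        raise ValueError("need at least one islet call set")
    if names is None:
        names = []
        for j, table in enumerate(islet_tables):
            ids = pd.unique(table["sample_id"]) if len(table) else []
            names.append(str(ids[0]) if len(ids) else f"islet{j + 1:02d}")
    keys = [pd.MultiIndex.from_frame(distinct_variants(t)[VARIANT_KEY]) for t in islet_tables]
    union = keys[0]
    for k in keys[1:]:
        union = union.union(k)
    matrix = pd.DataFrame(False, index=union, columns=names)
    for name, k in zip(names, keys):
        matrix.loc[k, name] = True
    matrix.index.names = VARIANT_KEY
    return matrix


def identify_ancestor_variants(
    islet_tables: list[pd.DataFrame],
    normal_table: pd.DataFrame | None = None,
    config: AncestorCallConfig = AncestorCallConfig(),
) -> pd.DataFrame:
    """Return variants whose islet presence fraction meets the threshold.

    Parameters
    ----------
    islet_tables : list of variant tables (>= 2 islets)
    normal_table : matched-normal variant table, or None
        When ``config.require_absent_in_normal`` is set, variants present in
        the normal are excluded (germline exclusion).
    config : AncestorCallConfig

    Returns
    -------
    DataFrame with columns chrom, pos, ref, alt, n_islets_carrying,
    presence_fraction (exactly carriers / n_islets), sorted by position.
    The >= comparison is inclusive: 27 of 30 islets passes a 0.9 threshold.
    """
    if len(islet_tables) == 0:
        raise ValueError("no islet call sets given")
    if len(islet_tables) < 2:
        raise ValueError("need at least two islet call sets to define presence")
    matrix = presence_matrix(islet_tables)
    n_islets = matrix.shape[1]
    carriers = matrix.sum(axis=1).to_numpy()
    fraction = carriers / n_islets
    keep = fraction >= config.islet_presence_threshold - _FRACTION_EPS
    out = matrix.index.to_frame(index=False)
    out["n_islets_carrying"] = carriers.astype(np.int64)
    out["presence_fraction"] = fraction
    out = out[keep]
    if config.require_absent_in_normal and normal_table is not None and len(normal_table):
        normal_keys = pd.MultiIndex.from_frame(distinct_variants(normal_table)[VARIANT_KEY])
        out_keys = pd.MultiIndex.from_frame(out[VARIANT_KEY])
        out = out[~out_keys.isin(normal_keys)]
    return out.sort_values(VARIANT_KEY, kind="mergesort").reset_index(drop=True)
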