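"""Join external quantitative data onto PlantMaps and aggregate record-level data.

Quantitative data (gene expression, metabolite levels, cell measurements …)
attach to a map at the *level* — the ROI name — not at individual polygons:
one value per distinct tissue/cell-type name paints every polygon of that
level.  :func:`merge_quant` performs the map-preserving left join;
:func:`aggregate_quant` collapses record-level input (e.g. per-cell
single-cell expression) to one value per level first; :func:`rename_levels`
harmonises dataset naming to the map's level names.
"""

from __future__ import annotations

import logging

import pandas as pd

from .map_model import ROI_ID, ROI_NAME, require_columns

logger = logging.getLogger(__name__)

AGG_STATS = ("mean", "median", "sum", "max")


class AmbiguousKeyError(ValueError):
    """The quantitative table holds more than one record for a key."""


class KeyCollisionError(ValueError):
    """Renaming mapped two keys with conflicting values onto one name."""


def merge_quant(
    map_df: pd.DataFrame,
    quant: pd.DataFrame,
    id_x: str = ROI_NAME,
    id_y: str | None = None,
) -> pd.DataFrame:
    """Left-join a quantitative table onto a PlantMap.

    Every map row is retained; rows whose ``id_x`` value has no match in
    ``quant`` carry missing values in the appended columns, so unmatched
    tissue still renders (grey) in heatmaps and the anatomy stays visible.
    All non-key quant columns are appended.  Matching is exact and
    case-sensitive after whitespace trimming — use :func:`rename_levels` to
    harmonise names, never rely on silent case folding.

    Parameters
    ----------
    map_df :
        PlantMap table; ``id_x`` defaults to ``ROI.name``.
    quant :
        At most one record per key; duplicate keys raise
        :class:`AmbiguousKeyError` (a silent row-multiplying join would break
        the one-row-per-vertex contract — aggregate first).
    id_x, id_y :
        Key column names in map and quant; ``id_y`` defaults to ``id_x``.
    """
    if id_y is None:
        id_y = id_x
    require_columns(map_df, [id_x], "map")
    require_columns(quant, [id_y], "quantitative table")

    q = quant.copy()
    q[id_y] = q[id_y].astype(str).str.strip()
    dup = q[id_y][q[id_y].duplicated()].unique()
    if len(dup):
        raise AmbiguousKeyError(
            f"duplicate key(s) in quantitative table: {sorted(dup)}; "
            "aggregate to one record per key first (see aggregate_quant)"
        )

    left_keys = map_df[id_x].astype(str).str.strip()
    matched = set(left_keys) & set(q[id_y])
    unmatched_quant = set(q[id_y]) - matched
    if unmatched_quant:
        logger.info(
            "%d quantitative record(s) match no map level and are dropped: %s",
            len(unmatched_quant), sorted(unmatched_quant),
        )

    merged = map_df.copy()
    append_cols = [c for c in q.columns if c != id_y]
    lookup = q.set_index(id_y)
    for c in append_cols:
        col = lookup[c].reindex(left_keys)
        merged[c] = col.to_numpy()
    return merged


def aggregate_quant(
    records: pd.DataFrame,
    group_col: str,
    value_col: str,
    stat: str = "mean",
) -> pd.DataFrame:
    """Collapse record-level data to one value per group.

    Typical use: per-cell single-cell expression → per-cell-type mean before
    merging onto a map.  Missing values are dropped before aggregation and
    groups are emitted in lexicographic order so output is deterministic.

    ``stat`` is one of ``mean``, ``median``, ``sum``, ``max``.
    """
    if stat not in AGG_STATS:
        raise ValueError(f"unknown stat {stat!r}; valid options: {', '.join(AGG_STATS)}")
    require_columns(records, [group_col, value_col], "records table")
    clean = records[[group_col, value_col]].dropna(subset=[value_col])
    clean = clean.assign(**{group_col: clean[group_col].astype(str).str.strip()})
    out = (
        clean.groupby(group_col, sort=True)[value_col]
        .agg(stat)
        .reset_index()
    )
    return out


def rename_levels(
    quant: pd.DataFrame,
    mapping: dict[str, str],
    key_column: str,
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """Rewrite key values to harmonise dataset naming with map level names.

    In strict mode every mapping key must be present in the table, and a
    rename that makes two records share a key is an error.  In lenient mode
    absent keys are ignored and post-rename duplicates with *equal* values in
    every other column are deduplicated; conflicting values always raise
    :class:`KeyCollisionError`.
    """
    require_columns(quant, [key_column], "quantitative table")
    out = quant.copy()
    keys = out[key_column].astype(str).str.strip()
    if strict:
        absent = [k for k in mapping if k not in set(keys)]
        if absent:
            raise KeyError(f"mapping key(s) not present in table: {absent}")
    out[key_column] = keys.map(lambda k: mapping.get(k, k))

    dup_keys = out[key_column][out[key_column].duplicated()].unique()
    if len(dup_keys):
        deduped = out.drop_duplicates()
        still_dup = deduped[key_column][deduped[key_column].duplicated()].unique()
        if len(still_dup) or strict:
            offenders = sorted(still_dup) if len(still_dup) else sorted(dup_keys)
            raise KeyCollisionError(
                f"renaming collapses distinct keys onto {offenders} "
                + ("with conflicting values" if len(still_dup) else "(strict mode)")
            )
        out = deduped.reset_index(drop=True)
    return out


def check_merged(merged: pd.DataFrame, value_col: str) -> None:
    """Assert the MergedMap contract: value constant within each ROI."""
    require_columns(merged, [ROI_ID, value_col], "merged map")
    bad = [
        int(rid)
        for rid, grp in merged.groupby(ROI_ID, sort=False)
        if grp[value_col].nunique(dropna=False) > 1
    ]
    if bad:
        raise ValueError(f"value column {value_col!r} varies within ROI.id(s) {bad}")
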