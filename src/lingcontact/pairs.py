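"""Statewise language-pair dataset construction.

Turns long feature tables into per-state binary variables, forms contact
rows (target language x each source-clade language, per state) and random
cross-family baseline rows (default 300 per feature, reused across the
feature's states), computes statewise agreement, and annotates areal
colocation plus the nested pair/broad-pair grouping the hierarchical models
expect.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .screen import ContactPair

logger = logging.getLogger(__name__)

#: Observation-table columns, in output order.
OBS_COLUMNS = [
    "state", "feature_id", "lang_target", "lang_other", "same_state",
    "G", "A", "area_combination", "pair_id", "broad_pair_id",
]


def binarize_states(feature_table: pd.DataFrame) -> pd.DataFrame:
    """One binary variable per feature state (state vs. not-state).

    Input is a CLDF-style long table (language_id, feature_id, value).
    Binary features yield a single variable — their two statewise
    binarizations carry identical agreement information.  Features with more
    than two observed states yield one variable per state.  Features with a
    single observed state are excluded (agreement would be constant).
    Missing values stay missing in every derived state variable.

    Returns a wide table indexed by language with one column per state id
    ``feature::state`` holding values in {0.0, 1.0, NaN}.
    """
    need = {"language_id", "feature_id", "value"}
    if not need <= set(feature_table.columns):
        raise InvalidInputError(f"feature table must carry columns {sorted(need)}")
    wide = feature_table.pivot_table(
        index="language_id", columns="feature_id", values="value", aggfunc="first", sort=False
    )
    out: dict[str, pd.Series] = {}
    for feat in wide.columns:
        col = wide[feat]
        states = sorted(col.dropna().unique())
        if len(states) < 2:
            logger.info("feature %s excluded: single observed state", feat)
            continue
        if len(states) == 2:
            states = states[:1]  # s vs not-s is agreement-equivalent to its complement
        for s in states:
            out[f"{feat}::{s}"] = (col == s).astype(float).where(col.notna())
    return pd.DataFrame(out, index=wide.index)


def agreement(v1: float, v2: float) -> float:
    """Statewise agreement: 1 if equal, 0 if unequal, NaN if either missing."""
    if pd.isna(v1) or pd.isna(v2):
        return float("nan")
    return float(v1 == v2)


def sample_baseline_pairs(
    languages: list[str],
    families: dict[str, str],
    n_per_feature: int = 300,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Uniform sample without replacement of unordered cross-family pairs.

    ``languages`` should already be restricted to those with non-missing data
    for the feature at hand.  Returns all available pairs with a warning when
    fewer than ``n_per_feature`` exist; raises when no cross-family pair
    exists at all.
    """
    candidates = [
        (a, b)
        for a, b in itertools.combinations(sorted(languages), 2)
        if families.get(a) != families.get(b)
    ]
    if not candidates:
        raise InvalidInputError("no cross-family language pair available")
    rng = np.random.default_rng(seed)
    if len(candidates) <= n_per_feature:
        if len(candidates) < n_per_feature:
            logger.warning(
                "only %d cross-family pairs available, requested %d",
                len(candidates), n_per_feature,
            )
        return candidates
    idx = rng.choice(len(candidates), size=n_per_feature, replace=False)
    return [candidates[i] for i in sorted(idx)]


def _area_column(area_coding: str) -> str:
    if area_coding not in ("autotyp", "glottolog"):
        raise InvalidInputError("area coding must be 'autotyp' or 'glottolog'")
    return f"area_{area_coding}"


def assemble_observations(
    contact_pairs: list[ContactPair],
    state_table: pd.DataFrame,
    metadata: pd.DataFrame,
    n_baseline: int = 300,
    area_coding: str = "autotyp",
    seed: int = 0,
) -> pd.DataFrame:
    """Build the full statewise observation table.

    Contact rows: for every state and contact pair, one row per source-clade
    language with data (a single pair id can thus be represented by several
    language pairs), G=1, carrying the pair/broad ids.  Baseline rows: for
    every feature, one random sample of cross-family pairs reused across the
    feature's states, G=0.  A=1 iff both languages share the configured area
    coding; ``area_combination`` is the sorted pair of area labels.
    Rows whose statewise agreement is missing are dropped.
    """
    if state_table.empty:
        raise InvalidInputError("state table is empty")
    area_col = _area_column(area_coding)
    need = {"language_id", "family", area_col}
    if not need <= set(metadata.columns):
        raise InvalidInputError(f"metadata must carry columns {sorted(need)}")
    meta = metadata.set_index("language_id")
    families = meta["family"].to_dict()
    areas = meta[area_col].to_dict()

    def require_lang(lang: str) -> None:
        if lang not in meta.index:
            raise InvalidInputError(f"language {lang!r} absent from metadata")

    states_by_feature: dict[str, list[str]] = {}
    for col in state_table.columns:
        feat = col.split("::", 1)[0]
        states_by_feature.setdefault(feat, []).append(col)

    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def annotate(lang_t: str, lang_o: str) -> tuple[int, str]:
        a1, a2 = str(areas[lang_t]), str(areas[lang_o])
        return int(a1 == a2), "|".join(sorted((a1, a2)))

    for feat, state_cols in states_by_feature.items():
        col0 = state_table[state_cols[0]]
        langs_with_data = [l for l in state_table.index[col0.notna()] if l in meta.index]
        try:
            baseline = sample_baseline_pairs(
                langs_with_data, families, n_per_feature=n_baseline,
                seed=int(rng.integers(2**31)),
            )
        except InvalidInputError:
            logger.warning("feature %s skipped: no cross-family baseline pair", feat)
            continue
        for state_col in state_cols:
            vals = state_table[state_col]
            for cp in contact_pairs:
                require_lang(cp.target_language)
                if cp.target_language not in state_table.index:
                    continue
                vt = vals.get(cp.target_language)
                for src in cp.source_clade_languages:
                    require_lang(src)
                    if src not in state_table.index or src == cp.target_language:
                        continue
                    y = agreement(vt, vals.get(src))
                    if pd.isna(y):
                        continue
                    a_i, combo = annotate(cp.target_language, src)
                    rows.append(
                        {
                            "state": state_col, "feature_id": feat,
                            "lang_target": cp.target_language, "lang_other": src,
                            "same_state": int(y), "G": 1, "A": a_i,
                            "area_combination": combo,
                            "pair_id": cp.pair_id, "broad_pair_id": cp.broad_pair_id,
                        }
                    )
            for a, b in baseline:
                y = agreement(vals.get(a), vals.get(b))
                if pd.isna(y):
                    continue
                a_i, combo = annotate(a, b)
                rows.append(
                    {
                        "state": state_col, "feature_id": feat,
                        "lang_target": a, "lang_other": b,
                        "same_state": int(y), "G": 0, "A": a_i,
                        "area_combination": combo,
                        "pair_id": None, "broad_pair_id": None,
                    }
                )
    if not rows:
        raise InvalidInputError("no observations could be assembled")
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def annotate_areas(
    observations: pd.DataFrame, metadata: pd.DataFrame, area_coding: str = "autotyp"
) -> pd.DataFrame:
    """(Re)compute A and area_combination from metadata; idempotent."""
    area_col = _area_column(area_coding)
    areas = metadata.set_index("language_id")[area_col].to_dict()
    out = observations.copy()
    missing = set(out["lang_target"]) | set(out["lang_other"])
    missing -= set(areas)
    if missing:
        raise InvalidInputError(f"languages absent from metadata: {sorted(missing)[:5]}")
    a1 = out["lang_target"].map(areas).astype(str)
    a2 = out["lang_other"].map(areas).astype(str)
    out["A"] = (a1 == a2).astype(int)
    out["area_combination"] = [
        "|".join(sorted(t)) for t in zip(a1, a2)
    ]
    return out
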