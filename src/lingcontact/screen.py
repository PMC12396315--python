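"""Candidate identification from per-K ancestry profiles.

Implements the two-component admixture screen over ADMIXTURE-style Q tables:
a population is a candidate if its two largest ancestry components jointly
reach ``top2_min`` (default 70%) with the smaller contributing at least
``minor_min`` (default 5%), consistently across at least ``min_k_levels``
distinct K.  Source proxies are populations carrying the relevant component
at ``source_purity_min`` (default 80%); triplets are filtered to keep exactly
one source inside the target's language family, yielding cross-family
contact pairs grouped by shared admixture source.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AncestryProfile:
    """One population's ancestry fractions at one assumed K."""

    population_id: str
    k: int
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if len(fr) != self.k:
            raise InvalidInputError(
                f"{self.population_id}: {len(fr)} fractions for K={self.k}"
            )
        if np.any(fr < -1e-9) or np.any(fr > 1 + 1e-9) or abs(fr.sum() - 1.0) > 1e-6:
            raise InvalidInputError(
                f"{self.population_id} at K={self.k}: fractions not on the simplex"
            )


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the per-K admixture screen."""

    top2_min: float = 0.70
    minor_min: float = 0.05
    min_k_levels: int = 5
    source_purity_min: float = 0.80
    k_range: tuple[int, ...] = tuple(range(12, 31))

    def __post_init__(self) -> None:
        if not 0 < self.minor_min < self.top2_min <= 1:
            raise InvalidInputError("need 0 < minor_min < top2_min <= 1")
        if self.min_k_levels < 1:
            raise InvalidInputError("min_k_levels must be >= 1")


@dataclass(frozen=True)
class TripletCandidate:
    """Target plus two source-proxy populations with per-K support counts."""

    target_pop: str
    source1_pop: str
    source2_pop: str
    n_k_admixed: int
    n_k_source1: int
    n_k_source2: int
    target_language: str | None = None
    source_languages: tuple[str, ...] = ()
    families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_k_source1 > self.n_k_admixed or self.n_k_source2 > self.n_k_admixed:
            raise InvalidInputError("source support cannot exceed admixture support")


@dataclass(frozen=True)
class ContactPair:
    """A curated (target language, unrelated source clade) contact pair."""

    pair_id: str
    broad_pair_id: str
    target_language: str
    source_clade_languages: tuple[str, ...]
    provenance: str = "admixture_screen"
    target_population: str | None = None
    source_population: str | None = None
    f3_impossible: bool = False


def _profile_matrix(q_table: pd.DataFrame) -> np.ndarray:
    m = q_table.to_numpy(dtype=float)
    if np.any(m < -1e-9) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-6):
        bad = q_table.index[np.abs(m.sum(axis=1) - 1.0) > 1e-6].tolist()
        raise InvalidInputError(f"rows not on the simplex: {bad[:5]}")
    return m


def top_two_components(fractions: np.ndarray) -> tuple[int, int]:
    """Indices of the largest and second-largest fraction.

    Ties are broken by the lowest component index, so the screen is
    deterministic and invariant to how equal-valued columns are ordered.
    """
    order = np.lexsort((np.arange(len(fractions)), -np.asarray(fractions)))
    return int(order[0]), int(order[1])


def passes_per_k(profile: AncestryProfile, cfg: ScreenConfig) -> tuple[bool, int, int]:
    """Apply the two-component rule at a single K.

    Returns (passes, major component index, minor component index).  Passes
    iff the two largest components sum to at least ``top2_min`` and the
    smaller of them is at least ``minor_min`` (below which the signal is
    treated as noise).
    """
    fr = np.asarray(profile.fractions, dtype=float)
    major, minor = top_two_components(fr)
    ok = (fr[major] + fr[minor] >= cfg.top2_min) and (fr[minor] >= cfg.minor_min)
    return bool(ok), major, minor


def detect_admixed_candidates(
    q_tables: dict[int, pd.DataFrame], cfg: ScreenConfig | None = None
) -> list[tuple[str, frozenset[int]]]:
    """Populations passing the per-K screen at >= min_k_levels distinct K.

    ``q_tables`` maps K to a population-indexed fraction table.  Returns
    ``(population, supporting K set)`` for each retained candidate, in
    population order of the first table.
    """
    cfg = cfg or ScreenConfig()
    if not q_tables:
        raise InvalidInputError("no ancestry tables supplied")
    if len(q_tables) < cfg.min_k_levels:
        raise InvalidInputError(
            f"profiles cover {len(q_tables)} K levels, need >= {cfg.min_k_levels}"
        )
    support: dict[str, set[int]] = {}
    order: list[str] = []
    for k in sorted(q_tables):
        q = q_tables[k]
        m = _profile_matrix(q)
        # vectorized equivalent of passes_per_k applied row-wise
        part = np.partition(m, m.shape[1] - 2, axis=1)
        minor = part[:, -2]
        ok_rows = (part[:, -1] + minor >= cfg.top2_min) & (minor >= cfg.minor_min)
        for pop, ok in zip(q.index, ok_rows):
            if pop not in support:
                support[pop] = set()
                order.append(pop)
            if ok:
                support[pop].add(k)
    out = [
        (pop, frozenset(ks))
        for pop in order
        if len(ks := support[pop]) >= cfg.min_k_levels
    ]
    logger.info("screen: %d/%d populations pass at >= %d K levels", len(out), len(order), cfg.min_k_levels)
    return out


def assign_source_proxies(
    candidate: tuple[str, frozenset[int]],
    q_tables: dict[int, pd.DataFrame],
    cfg: ScreenConfig | None = None,
) -> list[TripletCandidate]:
    """Emit all (source1, source2) proxy combinations for one candidate.

    At each supporting K, the major/minor components of the target are
    identified and every population carrying >= ``source_purity_min`` of that
    component is flagged as a proxy for the corresponding source.  The cross
    product of the two proxy sets (union over supporting K) is emitted with
    per-K support counts.  A candidate with no proxy for one component at any
    supporting K is dropped with a logged reason.
    """
    cfg = cfg or ScreenConfig()
    pop, ks = candidate
    if len(ks) < cfg.min_k_levels:
        raise InvalidInputError(f"candidate {pop!r} supported at only {len(ks)} K levels")
    s1_support: dict[str, int] = {}
    s2_support: dict[str, int] = {}
    for k in sorted(ks):
        q = q_tables[k]
        m = _profile_matrix(q)
        row = m[q.index.get_loc(pop)]
        ok, major, minor = passes_per_k(AncestryProfile(str(pop), k, tuple(row)), cfg)
        if not ok:
            raise InvalidInputError(f"candidate {pop!r} does not pass at its supporting K={k}")
        for other in q.index[m[:, major] >= cfg.source_purity_min]:
            s1_support[other] = s1_support.get(other, 0) + 1
        for other in q.index[m[:, minor] >= cfg.source_purity_min]:
            s2_support[other] = s2_support.get(other, 0) + 1
    if not s1_support or not s2_support:
        logger.warning(
            "candidate %s dropped: no proxy population at >= %.0f%% purity for the %s component",
            pop, 100 * cfg.source_purity_min, "major" if not s1_support else "minor",
        )
        return []
    triplets = [
        TripletCandidate(
            target_pop=str(pop),
            source1_pop=str(s1),
            source2_pop=str(s2),
            n_k_admixed=len(ks),
            n_k_source1=n1,
            n_k_source2=n2,
        )
        for (s1, n1), (s2, n2) in itertools.product(
            sorted(s1_support.items()), sorted(s2_support.items())
        )
        if s1 != s2
    ]
    return triplets


def screen_triplets(
    q_tables: dict[int, pd.DataFrame], cfg: ScreenConfig | None = None
) -> list[TripletCandidate]:
    """Full screen: candidates plus all their source-proxy triplets."""
    cfg = cfg or ScreenConfig()
    out: list[TripletCandidate] = []
    for cand in detect_admixed_candidates(q_tables, cfg):
        out.extend(assign_source_proxies(cand, q_tables, cfg))
    return out


def annotate_triplets(
    triplets: list[TripletCandidate], metadata: pd.DataFrame
) -> list[TripletCandidate]:
    """Attach language and family labels from the population metadata table.

    Populations without a language mapping are excluded with a warning rather
    than failing the run.
    """
    meta = metadata.set_index("population_id")
    out = []
    for t in triplets:
        pops = (t.target_pop, t.source1_pop, t.source2_pop)
        missing = [p for p in pops if p not in meta.index]
        if missing:
            logger.warning("triplet %s dropped: no language mapping for %s", pops, missing)
            continue
        langs = {p: str(meta.at[p, "language_glottocode"]) for p in pops}
        fams = {langs[p]: str(meta.at[p, "family"]) for p in pops}
        out.append(
            TripletCandidate(
                target_pop=t.target_pop,
                source1_pop=t.source1_pop,
                source2_pop=t.source2_pop,
                n_k_admixed=t.n_k_admixed,
                n_k_source1=t.n_k_source1,
                n_k_source2=t.n_k_source2,
                target_language=langs[t.target_pop],
                source_languages=(langs[t.source1_pop], langs[t.source2_pop]),
                families=fams,
            )
        )
    return out


def build_contact_pairs(
    triplets: list[TripletCandidate], metadata: pd.DataFrame
) -> list[ContactPair]:
    """Keep cross-family triplets and collapse them into contact pairs.

    A triplet survives iff exactly one source speaks a language of the
    target's family; the other (unrelated) source contributes its family's
    languages as the source clade.  Pairs are deduplicated by
    (target language, source clade family); pairs sharing the same source
    family collapse under one broad pair id.  Triplets whose unrelated source
    population *is* the target population are kept but flagged: F3 cannot be
    computed for them.
    """
    meta = metadata.set_index("population_id")
    required = {"language_glottocode", "family"}
    if not required <= set(metadata.columns):
        raise InvalidInputError(f"metadata must carry columns {sorted(required)}")
    fam_langs: dict[str, list[str]] = {}
    for _, row in metadata.iterrows():
        fam_langs.setdefault(str(row["family"]), []).append(str(row["language_glottocode"]))

    selected: dict[tuple[str, str], dict] = {}
    for t in triplets:
        for p in (t.target_pop, t.source1_pop, t.source2_pop):
            if p not in meta.index:
                raise InvalidInputError(f"population {p!r} missing from metadata")
        fam = {p: str(meta.at[p, "family"]) for p in (t.target_pop, t.source1_pop, t.source2_pop)}
        tfam = fam[t.target_pop]
        same = [s for s in (t.source1_pop, t.source2_pop) if fam[s] == tfam]
        if len(same) != 1:
            continue  # need exactly one related and one unrelated source
        unrelated = t.source2_pop if same == [t.source1_pop] else t.source1_pop
        key = (str(meta.at[t.target_pop, "language_glottocode"]), fam[unrelated])
        rec = selected.setdefault(
            key,
            {
                "target_pop": t.target_pop,
                "source_pop": unrelated,
                "f3_impossible": False,
            },
        )
        if unrelated == t.target_pop:
            rec["f3_impossible"] = True

    broad_of_family: dict[str, str] = {}
    pairs: list[ContactPair] = []
    counter_within: dict[str, int] = {}
    for (tlang, sfam), rec in sorted(selected.items()):
        if sfam not in broad_of_family:
            broad_of_family[sfam] = f"BP{len(broad_of_family) + 1:02d}"
        broad = broad_of_family[sfam]
        counter_within[broad] = counter_within.get(broad, 0) + 1
        pairs.append(
            ContactPair(
                pair_id=f"{broad}.{counter_within[broad]:02d}",
                broad_pair_id=broad,
                target_language=tlang,
                source_clade_languages=tuple(sorted(set(fam_langs[sfam]))),
                provenance="admixture_screen",
                target_population=rec["target_pop"],
                source_population=rec["source_pop"],
                f3_impossible=bool(rec["f3_impossible"]),
            )
        )
    logger.info("contact pairs: %d pairs under %d broad ids", len(pairs), len(broad_of_family))
    return pairs


def threshold_robustness(
    q_tables: dict[int, pd.DataFrame],
    cfg: ScreenConfig | None = None,
    alt_top2: tuple[float, ...] = (0.80, 0.90),
) -> pd.DataFrame:
    """Fraction of baseline candidates retained under stricter top-2 thresholds."""
    cfg = cfg or ScreenConfig()
    for alt in alt_top2:
        if alt <= cfg.top2_min:
            raise InvalidInputError("alternative thresholds must exceed the baseline")
    baseline = {pop for pop, _ in detect_admixed_candidates(q_tables, cfg)}
    rows = [{"top2_min": cfg.top2_min, "retained": 1.0 if baseline else float("nan")}]
    for alt in alt_top2:
        alt_cfg = ScreenConfig(
            top2_min=alt,
            minor_min=cfg.minor_min,
            min_k_levels=cfg.min_k_levels,
            source_purity_min=cfg.source_purity_min,
            k_range=cfg.k_range,
        )
        kept = {pop for pop, _ in detect_admixed_candidates(q_tables, alt_cfg)}
        frac = len(kept & baseline) / len(baseline) if baseline else float("nan")
        rows.append({"top2_min": alt, "retained": frac})
    return pd.DataFrame(rows)


def triplets_to_frame(triplets: list[TripletCandidate]) -> pd.DataFrame:
    """Longlist table of triplets for manual curation."""
    return pd.DataFrame(
        [
            {
                "target_pop": t.target_pop,
                "source1_pop": t.source1_pop,
                "source2_pop": t.source2_pop,
                "n_k_admixed": t.n_k_admixed,
                "n_k_source1": t.n_k_source1,
                "n_k_source2": t.n_k_source2,
                "target_language": t.target_language,
                "source_languages": ";".join(t.source_languages),
            }
            for t in triplets
        ]
    )


def contact_pairs_to_frame(pairs: list[ContactPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "broad_pair_id": p.broad_pair_id,
                "target_language": p.target_language,
                "source_clade_languages": ";".join(p.source_clade_languages),
                "provenance": p.provenance,
                "target_population": p.target_population,
                "source_population": p.source_population,
                "f3_impossible": p.f3_impossible,
            }
            for p in pairs
        ]
    )


def contact_pairs_from_frame(df: pd.DataFrame) -> list[ContactPair]:
    return [
        ContactPair(
            pair_id=str(r["pair_id"]),
            broad_pair_id=str(r["broad_pair_id"]),
            target_language=str(r["target_language"]),
            source_clade_languages=tuple(str(r["source_clade_languages"]).split(";")),
            provenance=str(r.get("provenance", "literature")),
            target_population=(None if pd.isna(r.get("target_population")) else str(r.get("target_population"))),
            source_population=(None if pd.isna(r.get("source_population")) else str(r.get("source_population"))),
            f3_impossible=bool(r.get("f3_impossible", False)),
        )
        for _, r in df.iterrows()
    ]
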