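"""Synthetic inputs with known ground truth for every pipeline stage.

The generators here produce the four kinds of input the pipeline consumes —
per-K ancestry-proportion tables, per-population allele counts, language
feature tables, and language-pair observation tables — from explicit,
seed-deterministic scenario descriptions.  Each generator returns (or embeds)
a truth record so that downstream stages (admixture screening, F3, the
hierarchical contact models) can be tested against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSpecError

#: Continent-scale contact-area labels at AUTOTYP-like granularity.
AUTOTYP_AREAS = (
    "Africa",
    "Europe",
    "Greater Mesopotamia",
    "Inner Asia",
    "Southeast Asia",
    "N Coast New Guinea",
    "Oceania",
    "Alaska-Oregon",
    "Basin and Plains",
    "Andean",
)

#: Coarser six-way labels mirroring Glottolog macroareas (sensitivity path).
MACROAREAS = (
    "Africa",
    "Eurasia",
    "Papunesia",
    "Australia",
    "North America",
    "South America",
)


@dataclass(frozen=True)
class AdmixtureEventSpec:
    """A planted two-source admixture event, visible at a set of K levels.

    ``alpha`` is the mixture fraction contributed by ``source1_pop``; the
    minor source contributes ``min(alpha, 1 - alpha)`` of the target's
    ancestry profile, so any ``alpha`` in ``[minor_min, 1 - minor_min]``
    survives the downstream two-component screen by construction.
    """

    target_pop: str
    source1_pop: str
    source2_pop: str
    alpha: float
    k_support: frozenset[int]
    families: dict[str, str] = field(default_factory=dict)
    areas: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidSpecError(f"alpha must lie in (0, 1), got {self.alpha}")
        if len(self.k_support) < 1:
            raise InvalidSpecError("k_support must name at least one K level")
        if self.source1_pop == self.source2_pop:
            raise InvalidSpecError("the two admixture sources must differ")
        object.__setattr__(self, "k_support", frozenset(int(k) for k in self.k_support))


@dataclass(frozen=True)
class ContactEffectTruth:
    """Ground-truth parameters of the hierarchical contact model.

    Log-odds scale throughout.  ``alpha_true`` is the global intercept,
    ``beta_A_true``/``beta_G_true`` the areal and genetic fixed effects.
    ``sigma_state`` scales the per-state varying intercept and both varying
    slopes; ``sigma_AA`` the per-area-combination pair; ``sigma_broad`` and
    ``sigma_pair`` the nested genetic-contact slopes.  ``rho`` is the shared
    correlation on all off-diagonals of the varying-effect covariances.
    ``per_state_effects`` may pin (intercept offset, area slope offset,
    genetic slope offset) for chosen states; unspecified states draw theirs
    from the multivariate normal.
    """

    alpha_true: float = 0.75
    beta_A_true: float = 0.2
    beta_G_true: float = 0.4
    sigma_state: float = 0.3
    sigma_AA: float = 0.15
    sigma_pair: float = 0.2
    sigma_broad: float = 0.2
    rho: float = 0.0
    per_state_effects: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("sigma_state", "sigma_AA", "sigma_pair", "sigma_broad"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        if not -1.0 < self.rho < 1.0:
            raise InvalidSpecError("rho must lie in (-1, 1)")


def _pop_names(n_pops: int) -> list[str]:
    return [f"POP{i:03d}" for i in range(n_pops)]


def _default_metadata(pops: list[str], events: list[AdmixtureEventSpec], rng: np.random.Generator) -> pd.DataFrame:
    """Metadata table: one language per population, families and areas.

    Event-provided family/area labels win; remaining populations get one
    family per population (so screened triplets are cross-family unless an
    event says otherwise) and areas cycling through the AUTOTYP-like labels.
    """
    fam_override: dict[str, str] = {}
    area_override: dict[str, str] = {}
    for ev in events:
        fam_override.update(ev.families)
        area_override.update(ev.areas)
    rows = []
    for i, pop in enumerate(pops):
        rows.append(
            {
                "population_id": pop,
                "language_glottocode": f"lang{i:04d}",
                "family": fam_override.get(pop, f"FAM_{i:03d}"),
                "area_autotyp": area_override.get(pop, AUTOTYP_AREAS[i % len(AUTOTYP_AREAS)]),
                "area_glottolog": MACROAREAS[i % len(MACROAREAS)],
            }
        )
    return pd.DataFrame(rows)


def simulate_q_profiles(
    n_pops: int,
    k_values: set[int],
    events: list[AdmixtureEventSpec],
    purity: float = 0.9,
    seed: int = 0,
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Simulate per-K ancestry tables in ADMIXTURE Q layout plus metadata.

    Every population owns a "home" ancestry component per K (index mod K).
    Non-event populations put a top share drawn from ``U(purity, purity+0.05)``
    (capped at 0.98) on their home component.  An event target instead splits
    its top share between the two sources' home components at each K in the
    event's ``k_support``: the minor source receives exactly
    ``min(alpha, 1-alpha)`` of the profile (capped at half the top share) and
    the major source the rest, so planted events pass the two-component screen
    whenever ``min(alpha, 1-alpha) >= minor_min``.  Residual mass is spread
    uniformly over the remaining components.

    Returns ``(q_tables, metadata)`` where ``q_tables[k]`` is a DataFrame
    indexed by population with columns ``C0..C{k-1}`` summing to 1.
    """
    if purity < 0.8:
        raise InvalidSpecError(f"purity must be >= 0.8, got {purity}")
    if not k_values:
        raise InvalidSpecError("k_values must be nonempty")
    pops = _pop_names(n_pops)
    pop_index = {p: i for i, p in enumerate(pops)}
    for ev in events:
        for p in (ev.target_pop, ev.source1_pop, ev.source2_pop):
            if p not in pop_index:
                raise InvalidSpecError(f"event names unknown population {p!r}")

    # One event may claim a population as target; a second claim overlaps.
    target_of: dict[str, AdmixtureEventSpec] = {}
    for ev in events:
        if ev.target_pop in target_of:
            raise InvalidSpecError(
                f"populations cannot receive two overlapping component assignments: {ev.target_pop!r}"
            )
        target_of[ev.target_pop] = ev
    for ev in events:
        for src in (ev.source1_pop, ev.source2_pop):
            if src in target_of and target_of[src].k_support & ev.k_support:
                raise InvalidSpecError(
                    f"population {src!r} is both an admixture target and a pure source at a shared K"
                )

    rng = np.random.default_rng(seed)
    k_sorted = sorted(int(k) for k in k_values)
    # Per-population top share, shared across K so profiles look consistent.
    top_cap = min(0.98, purity + 0.05)
    top_share = rng.uniform(purity, top_cap, size=n_pops)

    q_tables: dict[int, pd.DataFrame] = {}
    for k in k_sorted:
        home = np.arange(n_pops) % k
        q = np.zeros((n_pops, k))
        for i, pop in enumerate(pops):
            t = top_share[i]
            ev = target_of.get(pop)
            if ev is not None and k in ev.k_support:
                c1 = pop_index[ev.source1_pop] % k
                c2 = pop_index[ev.source2_pop] % k
                if c1 == c2:
                    raise InvalidSpecError(
                        f"sources of event on {pop!r} share ancestry component {c1} at K={k}; "
                        "choose source populations with index distance below the smallest K"
                    )
                minor = min(ev.alpha, 1.0 - ev.alpha)
                minor_share = min(minor, t / 2.0)
                major_share = t - minor_share
                if ev.alpha <= 0.5:
                    q[i, c1], q[i, c2] = minor_share, major_share
                else:
                    q[i, c1], q[i, c2] = major_share, minor_share
                used = {c1, c2}
            else:
                q[i, home[i]] = t
                used = {home[i]}
            rest = 1.0 - q[i].sum()
            others = [c for c in range(k) if c not in used]
            if others:
                q[i, others] = rest / len(others)
            else:  # K too small to leave spare components
                q[i, list(used)[0]] += rest
        q_tables[k] = pd.DataFrame(q, index=pops, columns=[f"C{c}" for c in range(k)])

    meta = _default_metadata(pops, events, rng)
    return q_tables, meta


def _bn_drift(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols drift: Beta(p(1-F)/F, (1-p)(1-F)/F) around p."""
    if f < 0:
        raise InvalidSpecError(f"drift parameter must be >= 0, got {f}")
    if f == 0:
        return p.copy()
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    return rng.beta(a, b)


def simulate_allele_counts(
    event: AdmixtureEventSpec | None,
    n_snps: int,
    n_diploid: dict[str, int],
    drift: float | dict[str, float] = 0.01,
    seed: int = 0,
    *,
    populations: tuple[str, str, str] | None = None,
    post_admixture_drift: float = 0.0,
    return_frequencies: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Simulate biallelic allele counts for a (target, source1, source2) trio.

    Ancestral frequencies are Uniform(0.05, 0.95); each source drifts from the
    ancestor by a Balding–Nichols Beta rescaling with its drift parameter F.
    With an ``event``, the target's true frequency is
    ``alpha * p1 + (1 - alpha) * p2`` (plus optional post-admixture drift);
    without one, the target is a pure drift descendant of source1 — the
    unadmixed control whose expected F3 is non-negative.  Observed counts are
    binomial draws of 2 * n_diploid chromosomes at the true frequencies.

    Returns a long table (snp_id, population_id, alt_count, total_count); with
    ``return_frequencies=True`` also the dict of true per-SNP frequencies.
    """
    if n_snps < 1:
        raise InvalidSpecError("n_snps must be >= 1")
    if event is not None:
        trio = (event.target_pop, event.source1_pop, event.source2_pop)
    elif populations is not None:
        trio = populations
    else:
        trio = ("TARGET", "SOURCE1", "SOURCE2")
    target, s1, s2 = trio
    drift_of = (lambda p: drift.get(p, 0.0)) if isinstance(drift, dict) else (lambda p: drift)
    if post_admixture_drift < 0:
        raise InvalidSpecError("post_admixture_drift must be >= 0")

    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    p1 = _bn_drift(p_anc, drift_of(s1), rng)
    p2 = _bn_drift(p_anc, drift_of(s2), rng)
    if event is not None:
        p_t = event.alpha * p1 + (1.0 - event.alpha) * p2
    else:
        p_t = _bn_drift(p1, drift_of(target), rng)
    if post_admixture_drift > 0:
        p_t = _bn_drift(p_t, post_admixture_drift, rng)

    freqs = {target: p_t, s1: p1, s2: p2}
    snp_ids = [f"snp{i:06d}" for i in range(n_snps)]
    frames = []
    for pop in trio:
        n_chr = 2 * int(n_diploid[pop])
        if n_chr < 1:
            raise InvalidSpecError(f"n_diploid[{pop!r}] must be >= 1")
        alt = rng.binomial(n_chr, freqs[pop])
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": snp_ids,
                    "population_id": pop,
                    "alt_count": alt,
                    "total_count": n_chr,
                }
            )
        )
    counts = pd.concat(frames, ignore_index=True)
    if return_frequencies:
        return counts, freqs
    return counts


def _corr_matrix(dim: int, rho: float) -> np.ndarray:
    r = np.full((dim, dim), rho)
    np.fill_diagonal(r, 1.0)
    return r


def simulate_pair_observations(
    truth: ContactEffectTruth,
    n_states: int,
    n_contact_pairs: int,
    n_baseline: int,
    area_labels: tuple[str, ...] = AUTOTYP_AREAS,
    seed: int = 0,
    n_broad: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw a language-pair observation table exactly under the full contact model.

    Each row's sharing probability is the inverse logit of the model's linear
    predictor: global intercept, per-state varying intercept, area-combination
    varying intercept, areal fixed effect plus per-state slope (times A), and
    genetic fixed effect plus per-state, per-area-combination and nested
    broad/pair slopes (times G).  Varying effects are drawn from multivariate
    normals whose covariances share a single off-diagonal correlation ``rho``.

    Returns the observation table and a truth record holding every realized
    group-level effect alongside the generating parameters.
    """
    if n_states < 1:
        raise InvalidSpecError("n_states must be >= 1")
    if n_baseline < 1:
        raise InvalidSpecError("need at least one baseline pair per state")
    rng = np.random.default_rng(seed)
    states = [f"ST{j:03d}" for j in range(n_states)]

    # Per-state varying effects (intercept, area slope, genetic slope).
    cov_state = truth.sigma_state**2 * _corr_matrix(3, truth.rho)
    state_eff = (
        rng.multivariate_normal(np.zeros(3), cov_state, size=n_states, method="cholesky")
        if truth.sigma_state > 0
        else np.zeros((n_states, 3))
    )
    for j, st in enumerate(states):
        if st in truth.per_state_effects:
            state_eff[j] = np.asarray(truth.per_state_effects[st], dtype=float)

    # Language inventory with areas: contact pairs get a target and a source
    # language each; a shared pool serves the baseline draws.
    n_pool = max(4 * n_contact_pairs, 40)
    pool = [f"L{i:04d}" for i in range(n_pool)]
    lang_area = {lang: area_labels[rng.integers(len(area_labels))] for lang in pool}

    if n_broad is None:
        n_broad = max(1, n_contact_pairs // 3)
    broad_ids = [f"B{b:02d}" for b in range(n_broad)]
    pair_rows = []
    for p in range(n_contact_pairs):
        pair_rows.append(
            {
                "pair_id": f"P{p:03d}",
                "broad_pair_id": broad_ids[p % n_broad],
                "lang_target": pool[2 * p],
                "lang_other": pool[2 * p + 1],
            }
        )
    broad_eff = {b: rng.normal(0.0, truth.sigma_broad) for b in broad_ids}
    pair_eff = {r["pair_id"]: rng.normal(0.0, truth.sigma_pair) for r in pair_rows}

    # Area-combination varying effects, drawn lazily per observed combination.
    cov_aa = truth.sigma_AA**2 * _corr_matrix(2, truth.rho)
    aa_eff: dict[str, np.ndarray] = {}

    def aa_effects(a1: str, a2: str) -> tuple[str, np.ndarray]:
        combo = "|".join(sorted((a1, a2)))
        if combo not in aa_eff:
            aa_eff[combo] = (
                rng.multivariate_normal(np.zeros(2), cov_aa, method="cholesky")
                if truth.sigma_AA > 0
                else np.zeros(2)
            )
        return combo, aa_eff[combo]

    rows = []
    for j, st in enumerate(states):
        a_s, bA_s, bG_s = state_eff[j]
        for r in pair_rows:
            t, o = r["lang_target"], r["lang_other"]
            a_i = int(lang_area[t] == lang_area[o])
            combo, (a_c, b_c) = aa_effects(lang_area[t], lang_area[o])
            eta = (
                truth.alpha_true
                + a_s
                + a_c
                + (truth.beta_A_true + bA_s) * a_i
                + (truth.beta_G_true + bG_s + b_c + broad_eff[r["broad_pair_id"]] + pair_eff[r["pair_id"]])
            )
            rows.append(
                {
                    "state": st,
                    "lang_target": t,
                    "lang_other": o,
                    "same_state": int(rng.random() < 1.0 / (1.0 + math.exp(-eta))),
                    "G": 1,
                    "A": a_i,
                    "area_combination": combo,
                    "pair_id": r["pair_id"],
                    "broad_pair_id": r["broad_pair_id"],
                }
            )
        for _ in range(n_baseline):
            i1, i2 = rng.choice(n_pool, size=2, replace=False)
            t, o = pool[i1], pool[i2]
            a_i = int(lang_area[t] == lang_area[o])
            combo, (a_c, b_c) = aa_effects(lang_area[t], lang_area[o])
            eta = truth.alpha_true + a_s + a_c + (truth.beta_A_true + bA_s) * a_i
            rows.append(
                {
                    "state": st,
                    "lang_target": t,
                    "lang_other": o,
                    "same_state": int(rng.random() < 1.0 / (1.0 + math.exp(-eta))),
                    "G": 0,
                    "A": a_i,
                    "area_combination": combo,
                    "pair_id": None,
                    "broad_pair_id": None,
                }
            )

    obs = pd.DataFrame(rows)
    truth_record = {
        "alpha_true": truth.alpha_true,
        "beta_A_true": truth.beta_A_true,
        "beta_G_true": truth.beta_G_true,
        "sigma_state": truth.sigma_state,
        "sigma_AA": truth.sigma_AA,
        "sigma_pair": truth.sigma_pair,
        "sigma_broad": truth.sigma_broad,
        "rho": truth.rho,
        "state_effects": {st: state_eff[j].tolist() for j, st in enumerate(states)},
        "aa_effects": {c: np.asarray(v).tolist() for c, v in aa_eff.items()},
        "broad_effects": broad_eff,
        "pair_effects": pair_eff,
    }
    return obs, truth_record


def simulate_feature_tables(
    n_langs: int,
    n_features: int,
    state_marginals: dict[str, float | list[float]] | None = None,
    seed: int = 0,
    n_families: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a CLDF-style long feature table plus language metadata.

    Features are independent across languages.  A scalar marginal q gives a
    binary feature with P(value "1") = q; a list of probabilities gives a
    multistate feature with those category weights.  Unspecified features
    default to binary with q drawn from U(0.2, 0.8).  Families are assigned
    round-robin so both related and unrelated pairs exist.
    """
    rng = np.random.default_rng(seed)
    langs = [f"L{i:04d}" for i in range(n_langs)]
    feats = [f"F{j:03d}" for j in range(n_features)]
    marginals = dict(state_marginals or {})
    for f in feats:
        if f not in marginals:
            marginals[f] = float(rng.uniform(0.2, 0.8))

    rows = []
    for f in feats:
        m = marginals[f]
        if isinstance(m, (int, float)):
            if not 0.0 < float(m) < 1.0:
                raise InvalidSpecError(f"marginal for {f} must be in (0,1), got {m}")
            values = np.where(rng.random(n_langs) < float(m), "1", "0")
        else:
            w = np.asarray(m, dtype=float)
            if np.any(w <= 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
                raise InvalidSpecError(f"multistate weights for {f} must be positive and sum to 1")
            values = np.array([f"s{c}" for c in rng.choice(len(w), size=n_langs, p=w)])
        for lang, v in zip(langs, values):
            rows.append({"language_id": lang, "feature_id": f, "value": v})
    table = pd.DataFrame(rows)

    if n_families is None:
        n_families = max(2, n_langs // 5)
    meta = pd.DataFrame(
        {
            "language_id": langs,
            "family": [f"FAM_{i % n_families:02d}" for i in range(n_langs)],
            "area_autotyp": [AUTOTYP_AREAS[i % len(AUTOTYP_AREAS)] for i in range(n_langs)],
            "area_glottolog": [MACROAREAS[i % len(MACROAREAS)] for i in range(n_langs)],
        }
    )
    return table, meta
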