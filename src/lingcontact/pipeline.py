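"""End-to-end orchestration: simulate -> screen -> F3 -> pairs -> fit -> meta -> report.

A :class:`RunConfig` fixes every path, threshold, sampler setting and
per-stage seed; :func:`run_pipeline` executes the stages in dependency
order, records a JSON manifest (inputs, seeds, outputs, stage status) and
skips stages whose outputs already exist when resuming.  A failed stage
marks itself failed in the manifest and downstream stages are skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .errors import LingContactError
from .f3 import f3_report_for_pairs
from .meta import collect_meta_observations, fit_main_meta, marginal_contrasts
from .models import (
    ModelSpec,
    build_design,
    delta_p,
    fit_model,
    state_effect_table,
)
from .pairs import assemble_observations, binarize_states
from .screen import (
    ScreenConfig,
    annotate_triplets,
    build_contact_pairs,
    contact_pairs_to_frame,
    screen_triplets,
    threshold_robustness,
    triplets_to_frame,
)
from .synthetic import (
    AdmixtureEventSpec,
    simulate_allele_counts,
    simulate_feature_tables,
    simulate_q_profiles,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "screen", "f3", "pairs", "fit", "meta", "report")


@dataclass
class RunConfig:
    """Plain-text configuration for a full pipeline run."""

    outdir: str = "lingcontact_run"
    seed: int = 0
    # simulation scenario
    n_pops: int = 40
    k_values: tuple[int, ...] = tuple(range(12, 31))
    n_events: int = 4
    purity: float = 0.9
    n_snps: int = 20000
    n_diploid: int = 15
    n_langs: int = 60
    n_features: int = 12
    # screening
    top2_min: float = 0.70
    minor_min: float = 0.05
    min_k_levels: int = 5
    source_purity_min: float = 0.80
    # pairs
    n_baseline: int = 100
    area_coding: str = "autotyp"
    # models
    models: tuple[str, ...] = ("m1",)
    chains: int = 2
    draws: int = 500
    warmup: int = 400
    # per-stage seeds, derived from `seed` unless set explicitly
    stage_seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(STAGES))
        for stage, child in zip(STAGES, children):
            self.stage_seeds.setdefault(stage, int(child.generate_state(1)[0] % (2**31)))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["k_values"] = list(self.k_values)
        d["models"] = list(self.models)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["k_values"] = tuple(d.get("k_values", range(12, 31)))
        d["models"] = tuple(d.get("models", ("m1",)))
        return cls(**d)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _default_events(cfg: RunConfig, rng: np.random.Generator) -> list[AdmixtureEventSpec]:
    """Plant a few well-separated admixture events among the populations."""
    events = []
    for e in range(cfg.n_events):
        base = 3 * e
        if base + 2 >= cfg.n_pops:
            break
        target, s1, s2 = (f"POP{base:03d}", f"POP{base + 1:03d}", f"POP{base + 2:03d}")
        # one source shares the target's family, the other is unrelated
        fams = {target: f"FAM_E{e}", s1: f"FAM_E{e}", s2: f"FAM_U{e}"}
        events.append(
            AdmixtureEventSpec(
                target_pop=target, source1_pop=s1, source2_pop=s2,
                alpha=float(rng.uniform(0.15, 0.45)),
                k_support=frozenset(list(cfg.k_values)[: max(5, len(cfg.k_values) // 2)]),
                families=fams,
            )
        )
    return events


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"config": str(out / "config.yaml"), "stages": {}}
    manifest_path = out / "manifest.json"

    def record(stage: str, status: str, outputs: dict[str, str] | None = None, error: str = ""):
        manifest["stages"][stage] = {
            "status": status,
            "seed": config.stage_seeds[stage],
            "outputs": outputs or {},
            "error": error,
        }
        io.write_json(manifest, manifest_path)

    state: dict = {}
    failed = False
    for stage in STAGES:
        if failed:
            record(stage, "skipped")
            continue
        try:
            outputs = _STAGE_FUNCS[stage](config, out, state, resume)
            record(stage, "completed", outputs)
        except LingContactError as exc:
            logger.error("stage %s failed: %s", stage, exc)
            record(stage, "failed", error=str(exc))
            failed = True
    manifest["digests"] = {
        name: _digest(Path(p))
        for st in manifest["stages"].values()
        for name, p in st["outputs"].items()
        if Path(p).is_file()
    }
    io.write_json(manifest, manifest_path)
    return manifest


def _stage_simulate(cfg: RunConfig, out: Path, state: dict, resume: bool) -> dict[str, str]:
    seed = cfg.stage_seeds["simulate"]
    rng = np.random.default_rng(seed)
    events = _default_events(cfg, rng)
    q_tables, pop_meta = simulate_q_profiles(
        cfg.n_pops, set(cfg.k_values), events, purity=cfg.purity, seed=seed
    )
    qdir = io.write_q_dir(q_tables, pop_meta, out / "qdir")
    counts = pd.concat(
        [
            simulate_allele_counts(
                ev, cfg.n_snps, {p: cfg.n_diploid for p in (ev.target_pop, ev.source1_pop, ev.source2_pop)},
                drift=0.02, seed=seed + 1 + i,
            )
            for i, ev in enumerate(events)
        ],
        ignore_index=True,
    ).drop_duplicates(subset=["snp_id", "population_id"])
    features, lang_meta = simulate_feature_tables(
        cfg.n_langs, cfg.n_features, seed=seed + 100
    )
    # align language metadata with the populations' languages so screened
    # pairs can be intersected with the feature tables
    lang_map = dict(zip(pop_meta["population_id"], pop_meta["language_glottocode"]))
    alias = {f"L{i:04d}": lang_map.get(f"POP{i:03d}") for i in range(cfg.n_pops)}
    features = features.assign(
        language_id=features["language_id"].map(lambda l: alias.get(l) or l)
    )
    lang_meta = lang_meta.assign(
        language_id=lang_meta["language_id"].map(lambda l: alias.get(l) or l)
    )
    fam_map = dict(zip(pop_meta["language_glottocode"], pop_meta["family"]))
    area_map = dict(zip(pop_meta["language_glottocode"], pop_meta["area_autotyp"]))
    garea_map = dict(zip(pop_meta["language_glottocode"], pop_meta["area_glottolog"]))
    lang_meta["family"] = [fam_map.get(l, f) for l, f in zip(lang_meta["language_id"], lang_meta["family"])]
    lang_meta["area_autotyp"] = [area_map.get(l, a) for l, a in zip(lang_meta["language_id"], lang_meta["area_autotyp"])]
    lang_meta["area_glottolog"] = [garea_map.get(l, a) for l, a in zip(lang_meta["language_id"], lang_meta["area_glottolog"])]
    outputs = {
        "qdir": str(qdir),
        "counts": str(io.write_table(counts, out / "allele_counts.tsv")),
        "features": str(io.write_table(features, out / "features.tsv")),
        "lang_meta": str(io.write_table(lang_meta, out / "language_metadata.tsv")),
    }
    state.update(q_tables=q_tables, pop_meta=pop_meta, counts=counts,
                 features=features, lang_meta=lang_meta, events=events)
    return outputs


def _stage_screen(cfg: RunConfig, out: Path, state: dict, resume: bool) -> dict[str, str]:
    scfg = ScreenConfig(
        top2_min=cfg.top2_min, minor_min=cfg.minor_min,
        min_k_levels=cfg.min_k_levels, source_purity_min=cfg.source_purity_min,
        k_range=cfg.k_values,
    )
    triplets = screen_triplets(state["q_tables"], scfg)
    triplets = annotate_triplets(triplets, state["pop_meta"])
    pairs = build_contact_pairs(triplets, state["pop_meta"])
    robustness = threshold_robustness(state["q_tables"], scfg)
    state.update(triplets=triplets, contact_pairs=pairs, screen_cfg=scfg)
    return {
        "longlist": str(io.write_table(triplets_to_frame(triplets), out / "longlist.tsv")),
        "contact_pairs": str(io.write_table(contact_pairs_to_frame(pairs), out / "contact_pairs.tsv")),
        "robustness": str(io.write_table(robustness, out / "threshold_robustness.tsv")),
    }


def _stage_f3(cfg: RunConfig, out: Path, state: dict, resume: bool) -> dict[str, str]:
    pairs = state["contact_pairs"]
    by_pair = {
        p.pair_id: [
            t for t in state["triplets"]
            if t.target_pop == p.target_population
            and p.source_population in (t.source1_pop, t.source2_pop)
        ]
        for p in pairs
    }
    report = f3_report_for_pairs(state["counts"], pairs, by_pair)
    state["f3_report"] = report
    return {"f3_report": str(io.write_table(report, out / "f3_report.tsv"))}


def _stage_pairs(cfg: RunConfig, out: Path, state: dict, resume: bool) -> dict[str, str]:
    states = binarize_states(state["features"])
    obs = assemble_observations(
        state["contact_pairs"], states, state["lang_meta"],
        n_baseline=cfg.n_baseline, area_coding=cfg.area_coding,
        seed=cfg.stage_seeds["pairs"],
    )
    state["observations"] = obs
    return {"observations": str(io.write_table(obs, out / "observations.tsv"))}


def _stage_fit(cfg: RunConfig, out: Path, state: dict, resume: bool) -> dict[str, str]:
    outputs = {}
    fits = {}
    for model_id in cfg.models:
        spec = ModelSpec.for_id(model_id)
        data = build_design(state["observations"], spec)
        fit = fit_model(
            spec, data, chains=cfg.chains, draws=cfg.draws, warmup=cfg.warmup,
            seed=cfg.stage_seeds["fit"],
        )
        fits[model_id] = fit
        summaries = []
        for condition in ("genetic", "area"):
            if (condition == "genetic" and not spec.includes_genetic) or (
                condition == "area" and not spec.includes_area
            ):
                continue
            es = delta_p(fit, "global", condition, force=True)
            summaries.append(dataclasses.asdict(es))
            table = state_effect_table(fit, condition, force=True)
            path = io.write_table(table, out / f"{model_id}_{condition}_states.tsv")
            outputs[f"{model_id}_{condition}_states"] = str(path)
        io.write_json(
            {"summaries": summaries, "diagnostics": fit.diagnostics},
            out / f"{model_id}_summary.json",
        )
        outputs[f"{model_id}_summary"] = str(out / f"{model_id}_summary.json")
    state["fits"] = fits
    return outputs


def _stage_meta(cfg: RunConfig, out: Path, state: dict, resume: bool) -> dict[str, str]:
    fits = {(mid, "main", "GBI"): f for mid, f in state["fits"].items()}
    meta_obs = collect_meta_observations(fits, force=True)
    if len(meta_obs) < 2:
        state["meta"] = None
        logger.warning("meta stage: fewer than 2 first-stage effects; skipped")
        return {}
    fit = fit_main_meta(meta_obs, seed=cfg.stage_seeds["meta"])
    contrasts = marginal_contrasts(fit)
    state["meta"] = contrasts
    return {
        "meta_observations": str(io.write_table(meta_obs, out / "meta_observations.tsv")),
        "meta_contrasts": str(io.write_table(contrasts, out / "meta_contrasts.tsv")),
    }


def _stage_report(cfg: RunConfig, out: Path, state: dict, resume: bool) -> dict[str, str]:
    path = out / "report.txt"
    path.write_text(report_text(cfg, state))
    return {"report": str(path)}


def report_text(cfg: RunConfig, state: dict) -> str:
    """Human-readable run summary with global and per-state effects."""
    lines = ["Contact-effect pipeline report", "=" * 32, ""]
    lines.append(f"populations screened: {cfg.n_pops}; contact pairs: {len(state.get('contact_pairs', []))}")
    if "f3_report" in state:
        sig = int(state["f3_report"]["significant"].sum())
        lines.append(f"F3-confirmed pairs (f3 < 0, z < -3): {sig}/{len(state['f3_report'])}")
    lines.append("")
    for model_id, fit in state.get("fits", {}).items():
        for condition in ("genetic", "area"):
            if (condition == "genetic" and not fit.spec.includes_genetic) or (
                condition == "area" and not fit.spec.includes_area
            ):
                continue
            es = delta_p(fit, "global", condition, force=True)
            lines.append(
                f"{model_id} {condition}: global delta-P = {100 * es.delta_p_mean:+.1f}% "
                f"[89% HPDI {100 * es.hpdi89_low:+.1f}%, {100 * es.hpdi89_high:+.1f}%], "
                f"P(>0) = {es.p_direction:.2f}"
            )
            table = state_effect_table(fit, condition, force=True)
            if len(table):
                pos = int((table["hpdi89_low"] > 0).sum())
                neg = int((table["hpdi89_high"] < 0).sum())
                zero = len(table) - pos - neg
                lines.append(
                    f"  states: {pos} borrowing (HPDI > 0), {neg} divergence (HPDI < 0), "
                    f"{zero} no effect (HPDI includes 0)"
                )
                top = table.sort_values("delta_p_mean", ascending=False).head(5)
                for _, r in top.iterrows():
                    lines.append(
                        f"    {r['state']}: delta-P {100 * r['delta_p_mean']:+.1f}% "
                        f"[{100 * r['hpdi89_low']:+.1f}%, {100 * r['hpdi89_high']:+.1f}%]"
                    )
    meta = state.get("meta")
    if meta is not None and len(meta):
        lines.append("")
        lines.append("meta-analysis contrasts (vs reference):")
        for _, r in meta.iterrows():
            lines.append(
                f"  {r['factor']}={r['level']} vs {r['reference']}: median {100 * r['median']:+.2f}% "
                f"[89% HPDI {100 * r['hpdi89_low']:+.2f}%, {100 * r['hpdi89_high']:+.2f}%]"
            )
    return "\n".join(lines) + "\n"


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "screen": _stage_screen,
    "f3": _stage_f3,
    "pairs": _stage_pairs,
    "fit": _stage_fit,
    "meta": _stage_meta,
    "report": _stage_report,
}
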