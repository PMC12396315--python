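"""Patterson's F3 admixture test with block-jackknife standard errors.

F3(T; A, B) averages (p_T - p_A)(p_T - p_B) over SNPs; a significantly
negative value indicates that T is admixed between sources related to A and
B.  Sample frequencies inflate the product by the sampling variance of p_T,
so each site subtracts the unbiased binomial-variance estimate
p_T(1 - p_T)/(n_T - 1), with n_T the chromosomes observed at the site.
Standard errors come from a weighted delete-one block jackknife over
contiguous SNP blocks, which is robust to local correlation along the
genome.  Significance follows the conventional rule: F3 < 0 with z < -3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, F3UndefinedError, InvalidInputError
from .screen import ContactPair, TripletCandidate

logger = logging.getLogger(__name__)

Z_THRESHOLD = -3.0


@dataclass(frozen=True)
class F3Result:
    f3: float
    se: float
    z: float
    n_snps_used: int
    n_blocks: int
    significant: bool
    degenerate: bool = False


def f3_per_snp(
    p_t: np.ndarray, p_a: np.ndarray, p_b: np.ndarray, n_t: np.ndarray
) -> np.ndarray:
    """Per-site F3 values with the small-sample bias correction.

    ``(p_t - p_a)(p_t - p_b) - p_t(1 - p_t)/(n_t - 1)``; the correction term
    is the unbiased estimator of Var(p̂_t) under binomial sampling of n_t
    chromosomes, so the site value is unbiased for the population-frequency
    product.  Sites with n_t < 2 are the caller's responsibility to skip.
    """
    p_t, p_a, p_b = (np.asarray(x, dtype=float) for x in (p_t, p_a, p_b))
    n_t = np.asarray(n_t, dtype=float)
    for name, arr in (("p_t", p_t), ("p_a", p_a), ("p_b", p_b)):
        if np.any((arr < 0) | (arr > 1)):
            raise InvalidInputError(f"{name} outside [0, 1]")
    if np.any(n_t < 2):
        raise InvalidInputError("n_t < 2: site must be skipped, not evaluated")
    return (p_t - p_a) * (p_t - p_b) - p_t * (1.0 - p_t) / (n_t - 1.0)


def weighted_block_jackknife(
    values: np.ndarray, block_sizes: np.ndarray
) -> tuple[float, float]:
    """Weighted delete-one-block jackknife mean and standard error.

    ``values`` holds per-block means, ``block_sizes`` the number of sites per
    block (the weights).  Uses the weighted-jackknife variance with
    pseudovalues tau_j = h_j * theta - (h_j - 1) * theta_(-j), h_j = n / m_j.
    """
    values = np.asarray(values, dtype=float)
    m = np.asarray(block_sizes, dtype=float)
    if len(values) != len(m) or len(values) < 2:
        raise InvalidInputError("need >= 2 blocks with matching weights")
    n = m.sum()
    theta = float(np.sum(m * values) / n)
    theta_del = (n * theta - m * values) / (n - m)  # leave-one-block-out estimates
    h = n / m
    theta_j = len(m) * theta - float(np.sum((1.0 - m / n) * theta_del))
    var = float(np.mean((h * theta - (h - 1.0) * theta_del - theta_j) ** 2 / (h - 1.0)))
    return theta, float(np.sqrt(var))


def _counts_wide(counts: pd.DataFrame, pops: tuple[str, str, str]) -> dict[str, pd.DataFrame]:
    need = {"snp_id", "population_id", "alt_count", "total_count"}
    if not need <= set(counts.columns):
        raise InvalidInputError(f"allele-count table must carry columns {sorted(need)}")
    sub = counts[counts["population_id"].isin(pops)]
    alt = sub.pivot_table(index="snp_id", columns="population_id", values="alt_count", sort=False)
    tot = sub.pivot_table(index="snp_id", columns="population_id", values="total_count", sort=False)
    return {"alt": alt, "tot": tot}


def f3_statistic(
    counts: pd.DataFrame,
    triplet: TripletCandidate | tuple[str, str, str],
    block_size: int = 500,
) -> F3Result:
    """F3 for one (target, source1, source2) triplet from allele counts.

    Sites missing any of the three populations are skipped and counted;
    blocks are contiguous runs of ``block_size`` usable SNPs in input order,
    weighted by their usable-site counts in the jackknife.
    """
    if isinstance(triplet, TripletCandidate):
        pops = (triplet.target_pop, triplet.source1_pop, triplet.source2_pop)
    else:
        pops = tuple(triplet)  # type: ignore[assignment]
    target, s1, s2 = pops
    if target == s1 or target == s2:
        raise F3UndefinedError(f"target {target!r} equals a source; F3 undefined")

    wide = _counts_wide(counts, pops)
    alt, tot = wide["alt"], wide["tot"]
    for p in pops:
        if p not in alt.columns:
            raise InvalidInputError(f"no allele counts for population {p!r}")
    a = alt[list(pops)].to_numpy(dtype=float)
    t = tot[list(pops)].to_numpy(dtype=float)
    usable = np.all(np.isfinite(a) & np.isfinite(t), axis=1) & (t[:, 0] >= 2) & np.all(t[:, 1:] >= 1, axis=1)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("f3(%s;%s,%s): skipped %d unusable sites", target, s1, s2, n_skipped)
    a, t = a[usable], t[usable]
    if a.shape[0] == 0:
        raise DegenerateInputError("no usable sites for this triplet")
    p_hat = a / t
    poly = np.any((a > 0) & (a < t), axis=1)
    if not np.any(poly):
        raise DegenerateInputError("all usable sites are monomorphic in all three populations")
    vals = f3_per_snp(p_hat[:, 0], p_hat[:, 1], p_hat[:, 2], t[:, 0])

    n_used = len(vals)
    n_blocks = max(2, int(np.ceil(n_used / block_size)))
    edges = np.linspace(0, n_used, n_blocks + 1).astype(int)
    block_means = np.array([vals[lo:hi].mean() for lo, hi in zip(edges[:-1], edges[1:])])
    sizes = np.diff(edges).astype(float)
    if np.ptp(vals) == 0.0:  # constant per-site values: SE is exactly zero
        f3 = float(vals[0])
        return F3Result(f3=f3, se=0.0, z=float("nan"), n_snps_used=n_used,
                        n_blocks=n_blocks, significant=False, degenerate=True)
    f3, se = weighted_block_jackknife(block_means, sizes)
    if se == 0.0:
        return F3Result(f3=f3, se=0.0, z=float("nan"), n_snps_used=n_used,
                        n_blocks=n_blocks, significant=False, degenerate=True)
    z = f3 / se
    return F3Result(
        f3=f3,
        se=se,
        z=z,
        n_snps_used=n_used,
        n_blocks=n_blocks,
        significant=bool(f3 < 0 and z < Z_THRESHOLD),
    )


def lowest_f3_over_triplets(
    counts: pd.DataFrame,
    triplets: list[TripletCandidate],
    block_size: int = 500,
) -> tuple[F3Result, TripletCandidate] | None:
    """Minimum-F3 result over a contact pair's computable triplets.

    Incomputable triplets (target equals a source, or degenerate counts) are
    passed over; returns None — the pair is flagged, not dropped — when no
    triplet is computable.
    """
    if not triplets:
        raise InvalidInputError("need at least one triplet")
    best: tuple[F3Result, TripletCandidate] | None = None
    for t in triplets:
        try:
            res = f3_statistic(counts, t, block_size=block_size)
        except (F3UndefinedError, DegenerateInputError, InvalidInputError) as exc:
            logger.info("triplet (%s;%s,%s) not computable: %s", t.target_pop, t.source1_pop, t.source2_pop, exc)
            continue
        if best is None or res.f3 < best[0].f3:
            best = (res, t)
    return best


def f3_report_for_pairs(
    counts: pd.DataFrame,
    pairs: list[ContactPair],
    triplets_by_pair: dict[str, list[TripletCandidate]],
    block_size: int = 500,
) -> pd.DataFrame:
    """Per-pair F3 report: lowest F3 triplet's statistics, or a flagged gap."""
    rows = []
    for p in pairs:
        trips = triplets_by_pair.get(p.pair_id, [])
        rec = {
            "pair_id": p.pair_id,
            "broad_pair_id": p.broad_pair_id,
            "target_language": p.target_language,
            "f3": np.nan,
            "se": np.nan,
            "z": np.nan,
            "n_snps": 0,
            "significant": False,
            "f3_computable": False,
        }
        if trips and not p.f3_impossible:
            best = lowest_f3_over_triplets(counts, trips, block_size=block_size)
            if best is not None:
                res, _ = best
                rec.update(
                    f3=res.f3, se=res.se, z=res.z, n_snps=res.n_snps_used,
                    significant=res.significant, f3_computable=not res.degenerate,
                )
        rows.append(rec)
    return pd.DataFrame(rows)
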