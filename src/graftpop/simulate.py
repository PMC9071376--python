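"""Synthetic graft populations with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: per-graft latent log2 fold-changes of metabolites drawn from a
block-correlated multivariate normal with origin-group mean shifts, a
small set of outlier grafts carrying a coordinated osmolyte signature,
sparse linear metabolite effects on yield traits on the log2FC scale,
correlated vegetative/fruit biomass traits, back-transformation to raw
scale via a reference mean, and multiplicative (lognormal) replicate
noise. The self-graft reference has latent log2FC identically zero, so
with zero replicate noise its fold-change row is exactly 1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (DEFAULT_REFERENCE_ID, DEFAULT_TRAIT_NAMES,
                        ORIGIN_LEVELS, PRIMARY_TRAITS, GraftPopulation,
                        derive_traits)

#: 54 metabolite labels. The first six form the osmolyte signature block;
#: the rest are realistic leaf GC-MS annotations but semantically arbitrary.
DEFAULT_METABOLITE_NAMES = (
    # block 0: osmolyte signature
    "sorbose", "galactose", "sucrose", "fructose", "myo-inositol", "proline",
    # block 1: TCA / organic acids
    "citrate", "malate", "fumarate", "succinate", "aspartate", "glutamate",
    # block 2: amino acids I
    "pyroglutamate", "glycine", "leucine", "isoleucine", "valine", "threonine",
    # block 3: amino acids II / amines
    "alanine", "serine", "GABA", "phenylalanine", "tyrosine", "methionine",
    # block 4
    "lysine", "ethanolamine", "putrescine", "5-hydroxytryptamine",
    "gluconate", "shikimate",
    # block 5
    "quinate", "ribonate", "saccharate", "caffeate", "erythronate",
    "threonate",
    # block 6
    "maleate", "trans-3-O-caffeoyl-D-quinate", "trans-5-O-caffeoyl-D-quinate",
    "glycerate", "arabinose", "glucose",
    # block 7
    "xylose", "trehalose", "maltose", "raffinose", "glycerol-3-phosphate",
    "fructose-6-phosphate",
    # block 8
    "glucose-6-phosphate", "threitol", "1,6-anhydro-beta-glucose",
    "unknown_1", "unknown_2", "unknown_3",
)

def default_block_membership(names: Sequence[str]) -> dict[str, int]:
    """Default correlation-block structure.

    The six osmolytes form the only six-member block (their coordinated
    response is the distinctive signature outlier grafts carry); the
    remaining metabolites fall into correlated pairs, so no small set of
    latent factors outside the signature can move six metabolites
    together.
    """
    out = {m: 0 for m in names[:6]}
    for i, m in enumerate(names[6:]):
        out[m] = 1 + i // 2
    return out


#: Rootstock-origin proportions of the emulated collection
#: (122 SLL, 45 SP, 36 SLC, 34 Other, 17 Wild of 254 heterografts).
DEFAULT_ORIGIN_COUNTS = {"SLL": 122, "SP": 45, "SLC": 36, "Other": 34,
                         "Wild": 17}

#: Reference-graft mean raw values used for back-transformation. MDA is
#: generated on a scale whose reference mean is 1 (i.e. fold-change-like),
#: metabolite relative abundances likewise.
DEFAULT_REFERENCE_MEANS = {
    "PH": 120.0, "BN": 15.0, "FN": 60.0, "FFW": 2000.0, "PFW": 1500.0,
    "FDW": 200.0, "PDW": 300.0, "MDA": 1.0,
}

#: Marginal sd of the latent log2FC for non-planted primary traits, and
#: mean shifts. BN sits well below the reference for almost all grafts.
DEFAULT_TRAIT_SD = {"PH": 0.25, "BN": 0.25, "FN": 0.35, "MDA": 0.6,
                    "FFW": 0.40, "FDW": 0.40, "PFW": 0.40, "PDW": 0.40}
DEFAULT_TRAIT_MEAN = {"BN": -0.5, "MDA": 0.1}

#: Pairs (partner, driver, correlation): the partner trait is generated to
#: correlate with the driver at the given level (vegetative vs fruit
#: biomass move together).
DEFAULT_TRAIT_COUPLING = (("PFW", "FFW", 0.8), ("PDW", "FDW", 0.8))


@dataclass
class SimulationTruth:
    """Ground truth of a generated population.

    ``beta`` holds, per predicted trait, the coefficient vector over
    metabolites on the log2FC scale *after* rescaling to the target R^2
    (filled in by :func:`generate_population` when generated from raw
    +-1 patterns). Coefficients outside ``true_support`` are exactly 0.
    """

    metabolite_names: tuple[str, ...] = DEFAULT_METABOLITE_NAMES
    beta: dict[str, np.ndarray] = field(default_factory=dict)
    true_support: dict[str, tuple[str, ...]] = field(default_factory=dict)
    target_r2: dict[str, float] = field(default_factory=dict)
    block_membership: dict[str, int] = field(default_factory=dict)
    rho_block: float = 0.7
    metabolite_sd: float = 0.35
    origin_shift: dict[str, np.ndarray] = field(default_factory=dict)
    origin_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ORIGIN_COUNTS))
    outlier_graft_ids: tuple[str, ...] | None = None
    n_outliers: int = 3
    osmolyte_block: tuple[str, ...] = DEFAULT_METABOLITE_NAMES[:6]
    outlier_offset: float = 2.0
    trait_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_SD))
    trait_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_MEAN))
    trait_coupling: tuple[tuple[str, str, float], ...] = DEFAULT_TRAIT_COUPLING
    reference_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_MEANS))
    replicate_cv: float = 0.12
    rng_seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.metabolite_names)
        if not self.block_membership:
            self.block_membership = default_block_membership(
                self.metabolite_names)
        for trait, r2 in self.target_r2.items():
            if not 0.0 < r2 < 1.0:
                raise ValueError(
                    f"target_r2 for {trait} must lie in (0,1), got {r2}")
        for trait, b in self.beta.items():
            b = np.asarray(b, dtype=float)
            if b.shape != (p,):
                raise ValueError(f"beta for {trait} must have length {p}")
            self.beta[trait] = b
            support = tuple(np.asarray(self.metabolite_names)[b != 0.0])
            if not support:
                raise ValueError(f"beta for {trait} has empty support")
            self.true_support[trait] = support
        if not -1.0 / 5.0 < self.rho_block < 1.0:
            raise ValueError("rho_block leaves the block covariance "
                             "non-positive-definite")

    def to_json(self, path: str) -> None:
        d = dataclasses.asdict(self)
        for trait in d["beta"]:
            d["beta"][trait] = list(d["beta"][trait])
        for origin in d["origin_shift"]:
            d["origin_shift"][origin] = list(d["origin_shift"][origin])
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2)


def default_truth(
    rng_seed: int = 0,
    *,
    predicted_traits: Sequence[str] = ("FFW", "FDW"),
    support_size: int = 5,
    target_r2: float | Mapping[str, float] = 0.5,
    replicate_cv: float = 0.12,
    n_outliers: int = 3,
) -> SimulationTruth:
    """Build the standard ground truth used throughout the test surface.

    Each predicted trait gets ``support_size`` nonzero coefficients of
    alternating sign, one per correlation block (skipping the osmolyte
    block), so the true predictors are mutually near-independent. Origin
    shifts are modest mean offsets of the organic-acid block for SP and of
    the sugar block for Wild rootstocks.
    """
    names = DEFAULT_METABOLITE_NAMES
    p = len(names)
    rng = np.random.default_rng(rng_seed)
    membership = default_block_membership(names)
    blocks_avail = sorted({b for b in membership.values() if b != 0})
    if isinstance(target_r2, Mapping):
        r2 = dict(target_r2)
    else:
        r2 = {t: float(target_r2) for t in predicted_traits}
    beta: dict[str, np.ndarray] = {}
    for k, trait in enumerate(predicted_traits):
        b = np.zeros(p)
        # one support metabolite per block (skipping the osmolyte block),
        # offset per trait so traits do not share predictors
        seen: set[int] = set()
        idx = []
        for j in range(support_size):
            pos = (k + 2 * j) % len(blocks_avail)
            while blocks_avail[pos] in seen:
                pos = (pos + 1) % len(blocks_avail)
            blk = blocks_avail[pos]
            seen.add(blk)
            members = [i for i, m in enumerate(names) if membership[m] == blk]
            idx.append(int(rng.choice(members)))
        signs = np.array([1.0 if j % 2 == 0 else -1.0
                          for j in range(support_size)])
        b[np.array(idx)] = signs
        beta[trait] = b
    shift_sp = np.zeros(p)
    shift_sp[6:12] = 0.3   # organic-acid block higher in SP
    shift_wild = np.zeros(p)
    shift_wild[42:48] = -0.3  # sugar block lower in Wild
    return SimulationTruth(
        metabolite_names=names,
        beta=beta,
        target_r2=r2,
        origin_shift={"SP": shift_sp, "Wild": shift_wild},
        replicate_cv=replicate_cv,
        n_outliers=n_outliers,
        rng_seed=rng_seed,
    )


def _block_mvn(rng: np.random.Generator, n: int, p: int,
               membership: np.ndarray, rho: float, sd: float) -> np.ndarray:
    """Draw n x p normals with within-block correlation rho, zero between."""
    z = np.empty((n, p))
    for blk in np.unique(membership):
        cols = np.flatnonzero(membership == blk)
        m = len(cols)
        corr = np.full((m, m), rho)
        np.fill_diagonal(corr, 1.0)
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("block correlation matrix is not positive "
                             f"definite (rho={rho}, block size {m})") from exc
        z[:, cols] = rng.standard_normal((n, m)) @ chol.T * sd
    return z


def _replicate_noise(rng: np.random.Generator, shape: tuple[int, ...],
                     cv: float) -> np.ndarray:
    """Mean-one lognormal multiplicative noise with the given CV."""
    if cv == 0.0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, shape) - sigma * sigma / 2.0)


def generate_population(
    truth: SimulationTruth,
    n_grafts: int = 255,
    n_replicates_range: tuple[int, int] = (3, 4),
    *,
    reference_id: str = DEFAULT_REFERENCE_ID,
) -> tuple[GraftPopulation, SimulationTruth]:
    """Generate a graft population realizing ``truth``.

    ``n_grafts`` counts analysis units including the self-graft reference
    (so the default 255 = 254 heterografts + reference). Returns the
    population together with a completed copy of the truth (outlier graft
    ids drawn if unset; beta rescaled to hit the target R^2 on the
    realized metabolite matrix).
    """
    if n_grafts < 20:
        raise ValueError("n_grafts must be >= 20")
    lo, hi = n_replicates_range
    if not (2 <= lo <= hi <= 6):
        raise ValueError("n_replicates_range must lie within [2, 6]")

    rng = np.random.default_rng(truth.rng_seed)
    names = list(truth.metabolite_names)
    p = len(names)
    n_het = n_grafts - 1
    graft_ids = [f"G{i:03d}" for i in range(1, n_het + 1)]

    # -- origins ----------------------------------------------------------
    origins_levels = [o for o in ORIGIN_LEVELS if truth.origin_counts.get(o, 0) > 0]
    counts = np.array([truth.origin_counts[o] for o in origins_levels], float)
    origins = rng.choice(origins_levels, size=n_het, p=counts / counts.sum())

    # -- latent metabolite log2FC -----------------------------------------
    membership = np.array([truth.block_membership[m] for m in names])
    Z = _block_mvn(rng, n_het, p, membership, truth.rho_block,
                   truth.metabolite_sd)
    for origin, shift in truth.origin_shift.items():
        Z[origins == origin] += np.asarray(shift, dtype=float)

    # -- outlier grafts with the osmolyte signature -----------------------
    if truth.outlier_graft_ids is None:
        chosen = rng.choice(n_het, size=truth.n_outliers, replace=False)
        outlier_ids = tuple(graft_ids[i] for i in sorted(chosen))
    else:
        outlier_ids = tuple(truth.outlier_graft_ids)
    osmo_cols = np.array([names.index(m) for m in truth.osmolyte_block])
    out_rows = np.array([graft_ids.index(g) for g in outlier_ids], dtype=int)
    if len(out_rows):
        Z[np.ix_(out_rows, osmo_cols)] += truth.outlier_offset

    # -- trait log2FC ------------------------------------------------------
    T = {}
    beta_scaled: dict[str, np.ndarray] = {}
    for trait in PRIMARY_TRAITS:
        sd = truth.trait_sd.get(trait, 0.3)
        mu = truth.trait_mean.get(trait, 0.0)
        if trait in truth.beta:
            r2 = truth.target_r2.get(trait, 0.5)
            s = Z @ truth.beta[trait]
            s_sd = s.std(ddof=1)
            if s_sd == 0:
                raise ValueError(f"planted signal for {trait} has zero "
                                 "variance")
            scale = np.sqrt(r2) * sd / s_sd
            b = truth.beta[trait] * scale
            beta_scaled[trait] = b
            T[trait] = (mu + Z @ b
                        + rng.normal(0.0, sd * np.sqrt(1.0 - r2), n_het))
        elif any(trait == partner for partner, _, _ in truth.trait_coupling):
            continue  # filled below from its driver
        else:
            T[trait] = mu + rng.normal(0.0, sd, n_het)
    for partner, driver, r in truth.trait_coupling:
        sd = truth.trait_sd.get(partner, 0.3)
        mu = truth.trait_mean.get(partner, 0.0)
        d = T[driver]
        d_std = (d - d.mean()) / d.std(ddof=1)
        T[partner] = (mu + r * sd * d_std
                      + rng.normal(0.0, sd * np.sqrt(1.0 - r * r), n_het))

    # -- back-transform and replicate expansion ---------------------------
    # reference graft has latent log2FC identically 0
    all_ids = [reference_id] + graft_ids
    log2fc_met = np.vstack([np.zeros((1, p)), Z])
    log2fc_trait = np.column_stack(
        [np.concatenate([[0.0], T[t]]) for t in PRIMARY_TRAITS])

    ref_means_trait = np.array([truth.reference_means[t]
                                for t in PRIMARY_TRAITS])
    raw_trait = ref_means_trait * np.exp2(log2fc_trait)
    raw_met = np.exp2(log2fc_met)  # reference metabolite abundance = 1

    n_reps = rng.integers(lo, hi + 1, size=n_grafts)
    rows: list[pd.DataFrame] = []
    derived_names = [t for t in DEFAULT_TRAIT_NAMES if t not in PRIMARY_TRAITS]
    for g in range(n_grafts):
        k = int(n_reps[g])
        prim = raw_trait[g] * _replicate_noise(rng, (k, len(PRIMARY_TRAITS)),
                                               truth.replicate_cv)
        mets = raw_met[g] * _replicate_noise(rng, (k, p), truth.replicate_cv)
        rep_ids = [f"R{j + 1}" for j in range(k)]
        trait_frames = []
        for j in range(k):
            full = derive_traits(dict(zip(PRIMARY_TRAITS, prim[j])))
            trait_frames.append(full)
        trait_df = pd.DataFrame(trait_frames, index=rep_ids)[
            list(PRIMARY_TRAITS) + derived_names]
        long_t = (trait_df.rename_axis("replicate").reset_index()
                  .melt(id_vars="replicate", var_name="feature",
                        value_name="value").dropna(subset=["value"]))
        met_df = pd.DataFrame(mets, index=rep_ids, columns=names)
        long_m = (met_df.rename_axis("replicate").reset_index()
                  .melt(id_vars="replicate", var_name="feature",
                        value_name="value"))
        both = pd.concat([long_t, long_m], ignore_index=True)
        both.insert(0, "graft_id", all_ids[g])
        rows.append(both)
    measurements = pd.concat(rows, ignore_index=True)

    meta = pd.DataFrame(
        {"accession": ["M82"] + [f"ACC{i:03d}" for i in range(1, n_het + 1)],
         "origin": ["SLL"] + list(origins)},
        index=pd.Index(all_ids, name="graft_id"))

    pop = GraftPopulation(
        measurements=measurements,
        meta=meta,
        trait_names=list(DEFAULT_TRAIT_NAMES),
        metabolite_names=names,
        reference_id=reference_id,
        # MDA is generated with reference mean 1, i.e. on a raw scale that
        # the standard ratio normalization applies to like any feature
        mda_is_fold_change=False,
    )
    completed = dataclasses.replace(
        truth,
        beta={t: b.copy() for t, b in beta_scaled.items()},
        outlier_graft_ids=outlier_ids,
    )
    return pop, completed
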