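"""Synthetic mother-child cohorts with known CST structure and planted transfer.

The generator emulates the study design this pipeline targets: vaginal
communities drawn from a mixture of Dirichlet components (low-diversity
types each dominated by one Lactobacillus-like ASV, plus one diverse
Gardnerella-like type), resampled at the second pregnancy visit with a
configurable stability; child fecal and airway communities with
compartment-specific baseline taxa; and a planted transfer mechanism in
which the child's log odds of carrying an ASV increase by a configurable
amount - settable per bacterial order and per delivery mode - when the
mother carries it.  Presence and abundance are decoupled (Bernoulli
presence, then Dirichlet-multinomial abundance at a lognormal sequencing
depth) so the planted effect lives exactly on the odds-ratio scale the
pipeline estimates.

Randomness is organized as one root seed with sub-streams keyed by
(dyad, compartment, timepoint), so results are bit-reproducible and
independent of iteration order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_core import (
    AbundanceTable,
    CHILD_TIMEPOINTS,
    SampleMetadata,
    TaxonomyTable,
)

logger = logging.getLogger(__name__)

#: The ten bacterial orders assigned round-robin by the default taxonomy;
#: these are the orders commonly rich enough in testable ASVs for the
#: order-level analysis.
DEFAULT_ORDERS = (
    "Clostridiales",
    "Lactobacillales",
    "Bacteroidales",
    "Selenomonadales",
    "Betaproteobacteriales",
    "Pseudomonadales",
    "Corynebacteriales",
    "Bifidobacteriales",
    "Enterobacteriales",
    "Bacillales",
)

_COMP_CODE = {"fecal": 1, "airway": 2}
_MODES = ("VAG", "CS-L", "CS-S")


@dataclass(frozen=True)
class CSTComponent:
    """One Dirichlet mixture component of the vaginal community model."""

    weight: float
    dominant_asv: int
    dominant_mean: float  # expected proportion of the dominant ASV
    background_conc: float  # total Dirichlet mass spread over the other ASVs
    #: ASVs absent from this community type (zero Dirichlet mass).  The
    #: diverse type is depleted of the Lactobacillus-like dominants, its
    #: defining feature.
    depleted: tuple[int, ...] = ()

    def alpha(self, n_asvs: int) -> np.ndarray:
        if self.dominant_asv >= n_asvs:
            raise ValidationError(
                f"dominant ASV index {self.dominant_asv} >= n_asvs {n_asvs}"
            )
        background = [
            j for j in range(n_asvs) if j != self.dominant_asv and j not in self.depleted
        ]
        if not background:
            raise ValidationError("component has no background ASVs")
        a = np.zeros(n_asvs)
        a[background] = self.background_conc / len(background)
        a[self.dominant_asv] = self.dominant_mean / (1 - self.dominant_mean) * self.background_conc
        return a


#: Five dominated, low-diversity types plus one diverse type (depleted of
#: the five dominants).
DEFAULT_CST_SPEC = (
    CSTComponent(0.30, 0, 0.95, 0.5),
    CSTComponent(0.20, 1, 0.95, 0.5),
    CSTComponent(0.15, 2, 0.92, 0.5),
    CSTComponent(0.10, 3, 0.92, 0.5),
    CSTComponent(0.10, 4, 0.90, 0.5),
    CSTComponent(0.15, 5, 0.35, 8.0, depleted=(0, 1, 2, 3, 4)),
)


def default_child_baseline(n_asvs: int) -> dict[str, np.ndarray]:
    """Compartment-specific Dirichlet concentrations for child communities.

    Each compartment favors a different third of the ASV pool, giving the
    fecal and airway compartments distinct baseline taxa while keeping
    overlap with the vaginal pool.
    """
    out = {}
    for comp, residue in (("fecal", 0), ("airway", 1)):
        conc = np.full(n_asvs, 0.05)
        conc[np.arange(n_asvs) % 3 == residue] = 0.4
        out[comp] = conc
    return out


def default_taxonomy(n_asvs: int) -> TaxonomyTable:
    """Round-robin assignment of ASVs to the ten default orders."""
    rows = []
    for j in range(n_asvs):
        order = DEFAULT_ORDERS[j % len(DEFAULT_ORDERS)]
        rows.append(
            {
                "asv_id": f"ASV{j:04d}",
                "kingdom": "Bacteria",
                "phylum": f"P_{order}",
                "class": f"C_{order}",
                "order": order,
                "family": f"F_{order}",
                "genus": f"G_{order}_{j}",
            }
        )
    return TaxonomyTable(pd.DataFrame(rows))


@dataclass
class SimulationParams:
    """Cohort-level knobs; defaults are the generator's study conditions."""

    n_dyads: int = 665
    n_asvs: int = 150
    cst_spec: tuple[CSTComponent, ...] = DEFAULT_CST_SPEC
    stability: float = 0.85  # P(same CST component at week 36)
    child_baseline: dict[str, np.ndarray] | None = None
    #: (order, delivery mode) -> log odds added to child presence when the
    #: mother carries the ASV.  Missing keys mean no transfer.
    transfer_log_or: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline_presence_logit: dict[str, float] = field(
        default_factory=lambda: {"fecal": -1.4, "airway": -1.8}
    )
    depth_model: tuple[float, float, int] = (np.log(30000.0), 0.7, 1000)
    mode_probs: tuple[float, float, float] = (0.78, 0.12, 0.10)
    compartments: tuple[str, ...] = ("fecal", "airway")
    #: optional restriction of the sampling schedule, e.g. {"fecal": (7,)};
    #: None means the full schedule for each compartment
    timepoints: dict[str, tuple[int, ...]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        weights = [c.weight for c in self.cst_spec]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError("CST mixture weights must sum to 1")
        if any(c.background_conc <= 0 or not 0 < c.dominant_mean < 1 for c in self.cst_spec):
            raise ValidationError("component concentrations must be positive")
        if abs(sum(self.mode_probs) - 1.0) > 1e-9:
            raise ValidationError("mode_probs must sum to 1")
        if self.depth_model[2] < 1:
            raise ValidationError("depth floor must be >= 1")
        if not 0 <= self.stability <= 1:
            raise ValidationError("stability must lie in [0, 1]")
        dominants = [c.dominant_asv for c in self.cst_spec]
        if max(dominants, default=-1) >= self.n_asvs:
            raise ValidationError("n_asvs smaller than the largest dominant-ASV index")
        if self.timepoints is not None:
            for comp, tps in self.timepoints.items():
                bad = set(tps) - set(CHILD_TIMEPOINTS[comp])
                if bad:
                    raise ValidationError(
                        f"{comp} timepoints must be within {CHILD_TIMEPOINTS[comp]}; got {sorted(bad)}"
                    )

    def schedule(self, compartment: str) -> tuple[int, ...]:
        if self.timepoints is not None and compartment in self.timepoints:
            return tuple(self.timepoints[compartment])
        return CHILD_TIMEPOINTS[compartment]

    def baseline(self) -> dict[str, np.ndarray]:
        return (
            self.child_baseline
            if self.child_baseline is not None
            else default_child_baseline(self.n_asvs)
        )


def _depth(rng: np.random.Generator, model: tuple[float, float, int]) -> int:
    meanlog, sdlog, floor = model
    return max(int(np.round(np.exp(rng.normal(meanlog, sdlog)))), int(floor))


def _asv_ids(n_asvs: int) -> list[str]:
    return [f"ASV{j:04d}" for j in range(n_asvs)]


def simulate_vaginal(
    params: SimulationParams, seed: int | None = None
) -> tuple[AbundanceTable, AbundanceTable, pd.DataFrame]:
    """Vaginal communities at gestational weeks 24 and 36.

    Each mother's week-24 community is drawn from one mixture component;
    at week 36 the composition is resampled from the same component with
    probability ``params.stability``, else from a freshly drawn component.
    Returns the two count tables and the true component labels.
    """
    seed = params.seed if seed is None else seed
    weights = np.array([c.weight for c in params.cst_spec])
    alphas = [c.alpha(params.n_asvs) for c in params.cst_spec]
    ids24, ids36, rows24, rows36, truth = [], [], [], [], []
    for i in range(params.n_dyads):
        rng = np.random.default_rng([seed, 0, i])
        z24 = int(rng.choice(len(weights), p=weights))
        z36 = z24 if rng.random() < params.stability else int(rng.choice(len(weights), p=weights))
        for z, ids, rows in ((z24, ids24, rows24), (z36, ids36, rows36)):
            alpha = alphas[z]
            support = alpha > 0
            p = np.zeros(params.n_asvs)
            p[support] = rng.dirichlet(alpha[support])
            counts = rng.multinomial(_depth(rng, params.depth_model), p)
            rows.append(counts)
        ids24.append(f"M{i:04d}-V24")
        ids36.append(f"M{i:04d}-V36")
        truth.append({"dyad_id": f"D{i:04d}", "true_cst_w24": z24, "true_cst_w36": z36})
    asvs = _asv_ids(params.n_asvs)
    shape = (params.n_dyads, params.n_asvs)
    w24 = AbundanceTable(ids24, asvs, np.array(rows24, dtype=np.int64).reshape(shape))
    w36 = AbundanceTable(ids36, asvs, np.array(rows36, dtype=np.int64).reshape(shape))
    return w24, w36, pd.DataFrame(truth)


def draw_modes(params: SimulationParams, seed: int | None = None) -> pd.Series:
    """One delivery mode per dyad, drawn from ``mode_probs``."""
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng([seed, 9])
    modes = rng.choice(_MODES, size=params.n_dyads, p=np.array(params.mode_probs))
    return pd.Series(modes, index=[f"D{i:04d}" for i in range(params.n_dyads)], name="delivery")


def simulate_children(
    vaginal_w36: AbundanceTable,
    params: SimulationParams,
    seed: int | None = None,
    modes: pd.Series | None = None,
) -> tuple[dict[tuple[str, int], AbundanceTable], pd.DataFrame]:
    """Child communities for every (compartment, timepoint) of the schedule.

    Child presence of ASV j is Bernoulli with
    logit = baseline_presence_logit[compartment]
          + transfer_log_or[(order(j), mode)] * 1[mother carries j];
    abundances of the present ASVs follow the compartment's Dirichlet
    baseline restricted to the present set, with multinomial counts at a
    lognormal depth.  The delivery mode is drawn once per dyad and shared
    by all of that child's samples.  Returns the tables keyed by
    (compartment, timepoint_days) and the child metadata rows.
    """
    seed = params.seed if seed is None else seed
    n_dyads = vaginal_w36.shape[0]
    if n_dyads != params.n_dyads:
        raise ValidationError("vaginal table size does not match params.n_dyads")
    taxonomy = default_taxonomy(params.n_asvs)
    orders = taxonomy.orders(vaginal_w36.asv_ids).to_numpy()
    if modes is None:
        modes = draw_modes(params, seed)
    mother_present = vaginal_w36.counts >= 1
    baseline = params.baseline()

    missing_keys = {
        (o, m)
        for o in sorted(set(orders))
        for m in _MODES
        if (o, m) not in params.transfer_log_or
    }
    if params.transfer_log_or and missing_keys:
        logger.info(
            "transfer_log_or missing %d (order, mode) keys; treated as 0", len(missing_keys)
        )

    # per-ASV transfer effect by mode, from the order-level mapping
    beta = {
        m: np.array([params.transfer_log_or.get((o, m), 0.0) for o in orders])
        for m in _MODES
    }

    tables: dict[tuple[str, int], AbundanceTable] = {}
    meta_rows = []
    for comp in params.compartments:
        base_logit = params.baseline_presence_logit[comp]
        conc = baseline[comp]
        for tp in params.schedule(comp):
            ids, rows = [], []
            for i in range(n_dyads):
                rng = np.random.default_rng([seed, _COMP_CODE[comp], tp, i])
                mode = modes.iloc[i]
                logit = base_logit + beta[mode] * mother_present[i]
                present = rng.random(params.n_asvs) < 1.0 / (1.0 + np.exp(-logit))
                counts = np.zeros(params.n_asvs, dtype=np.int64)
                if present.any():
                    # every present ASV gets >= 1 read so that count-level
                    # presence coincides with the latent Bernoulli draw and
                    # the planted log odds live exactly on the presence scale
                    k = int(present.sum())
                    depth = max(_depth(rng, params.depth_model), k)
                    p = rng.dirichlet(conc[present])
                    counts[present] = 1 + rng.multinomial(depth - k, p)
                sid = f"C{i:04d}-{comp[0].upper()}{tp:03d}"
                ids.append(sid)
                rows.append(counts)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "subject_id": f"C{i:04d}",
                        "dyad_id": f"D{i:04d}",
                        "role": "child",
                        "compartment": comp,
                        "timepoint_days": tp,
                        "delivery": mode,
                    }
                )
            tables[(comp, tp)] = AbundanceTable(
                ids,
                list(vaginal_w36.asv_ids),
                np.array(rows, dtype=np.int64).reshape(n_dyads, params.n_asvs),
            )
    return tables, pd.DataFrame(meta_rows)


@dataclass
class CohortBundle:
    """Everything one simulated cohort produces, plus its ground truth."""

    params: SimulationParams
    vaginal_w24: AbundanceTable
    vaginal_w36: AbundanceTable
    child_tables: dict[tuple[str, int], AbundanceTable]
    metadata: SampleMetadata
    taxonomy: TaxonomyTable
    truth: dict


def simulate_cohort(params: SimulationParams, seed: int | None = None) -> CohortBundle:
    """Compose the vaginal and child generators into a full cohort.

    The ``truth`` sidecar records the true CST component labels, the drawn
    delivery modes, and the planted transfer log odds for every (order,
    mode) pair - zeros included - so downstream recovery can be scored.
    """
    seed = params.seed if seed is None else seed
    w24, w36, cst_truth = simulate_vaginal(params, seed)
    modes = draw_modes(params, seed)
    child_tables, child_meta = simulate_children(w36, params, seed, modes)
    taxonomy = default_taxonomy(params.n_asvs)
    mother_rows = []
    for i in range(params.n_dyads):
        for week, sid in ((24, f"M{i:04d}-V24"), (36, f"M{i:04d}-V36")):
            mother_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": f"M{i:04d}",
                    "dyad_id": f"D{i:04d}",
                    "role": "mother",
                    "compartment": "vaginal",
                    "timepoint_days": week,
                    "delivery": modes.iloc[i],
                }
            )
    from .io_core import METADATA_COLUMNS

    frames = [pd.DataFrame(mother_rows), child_meta]
    meta_df = pd.concat([f for f in frames if len(f)], ignore_index=True) if any(
        len(f) for f in frames
    ) else pd.DataFrame({c: pd.Series(dtype=str) for c in METADATA_COLUMNS})
    meta = SampleMetadata(meta_df)
    all_orders = sorted(set(taxonomy.frame["order"]))
    truth = {
        "true_cst": cst_truth,
        "modes": modes,
        "transfer_log_or": {
            (o, m): params.transfer_log_or.get((o, m), 0.0)
            for o in all_orders
            for m in _MODES
        },
    }
    return CohortBundle(params, w24, w36, child_tables, meta, taxonomy, truth)


def planted_transfer(
    log_or: float,
    modes: tuple[str, ...] = ("VAG",),
    orders: tuple[str, ...] = DEFAULT_ORDERS,
) -> dict[tuple[str, str], float]:
    """Uniform planted-transfer mapping: one log OR for the given modes/orders."""
    return {(o, m): float(log_or) for o in orders for m in modes}
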