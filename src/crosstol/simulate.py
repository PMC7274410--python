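"""Synthetic inputs with planted ground truth for every pipeline stage.

Real multi-stress proteome studies of this kind publish spot tables and
figures but rarely deposit machine-readable densitometry, so each analysis
stage here is exercised on generated data whose answer is known:

* a sparse directed interaction network (DAG) whose sources follow smooth
  exogenous stress transients (a gamma-shaped pulse on a baseline, the
  rise-then-relax kinetics typical of acclimation responses) and whose
  downstream proteins obey the power-law kinetics of
  :mod:`crosstol.ssystem`, sampled on a short time course with
  multiplicative log-normal noise;
* a replicated 2-DE spot table with planted ≥1.5-fold up/down effects
  across the four conditions;
* qPCR Ct tables with planted ΔΔCt shifts against a constant-mean actin
  reference;
* enzyme activity tables with planted fold effects and an optional
  not-detected sentinel.

All generators are pure functions of (seed, configuration): the same seed
regenerates bit-identical data. Ground truth is serialized alongside each
dataset as JSON.

The packaged spot catalog lists the 39 stress-responsive soybean leaf spots
(accessions and functional categories: 14 metabolism, 7 response-to-heat,
7 photosynthesis, 5 redox, 3 protein-refolding, 3 others) used to label
generated proteins.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .srp import CONDITIONS, CONTROL, STRESSES, UP, DOWN, UNCHANGED
from .ssystem import SSystemParams, Trajectory

__all__ = [
    "QPCR_GENES",
    "TrueEdge",
    "NetworkTruth",
    "GroundTruth",
    "load_spot_catalog",
    "generate_network",
    "simulate_timecourse",
    "generate_spot_table",
    "generate_qpcr",
    "generate_enzyme_table",
    "default_times",
]

#: Transcripts assayed by qPCR (stress-responsive proteins followed at the
#: transcript level), actin-normalized.
QPCR_GENES = (
    "ascorbate_peroxidase",
    "calreticulin",
    "catalase",
    "chalcone_flavone_isomerase",
    "heat_shock_protein_70",
    "peroxidase",
    "peroxiredoxin",
    "serine_hydroxymethyltransferase_5",
    "superoxide_dismutase",
)

#: Span of the stress time course in days (three weeks).
TIMECOURSE_DAYS = 21.0


def default_times(n_points: int = 8, span_days: float = TIMECOURSE_DAYS):
    """Evenly spaced sampling times over the stress period."""
    return np.linspace(0.0, span_days, n_points)


def load_spot_catalog() -> pd.DataFrame:
    """The packaged 39-spot catalog (spot_id, accession, category, ...)."""
    ref = resources.files("crosstol.data").joinpath("spot_catalog.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"spot_id": str})


@dataclass(frozen=True)
class TrueEdge:
    """A planted regulator→target interaction with its kinetics."""

    regulator: str
    target: str
    params: SSystemParams


@dataclass
class NetworkTruth:
    """A planted interaction network: nodes, categories and edges."""

    nodes: list[str]
    categories: dict[str, str]
    edges: list[TrueEdge]
    seed: int

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.regulator, e.target) for e in self.edges}

    def sources(self) -> list[str]:
        targets = {e.target for e in self.edges}
        return [n for n in self.nodes if n not in targets]


@dataclass
class GroundTruth:
    """Everything planted into one generated dataset, JSON-serializable."""

    seed: int
    network: NetworkTruth | None = None
    planted_srp: dict[str, dict[str, str]] = field(default_factory=dict)
    planted_ddct: dict[str, dict[str, float]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "planted_srp": self.planted_srp,
            "planted_ddct": self.planted_ddct,
            "config": self.config,
            "network": None,
        }
        if self.network is not None:
            payload["network"] = {
                "nodes": self.network.nodes,
                "categories": self.network.categories,
                "seed": self.network.seed,
                "edges": [
                    {
                        "regulator": e.regulator,
                        "target": e.target,
                        "params": {
                            k: v
                            for k, v in asdict(e.params).items()
                            if k != "g_bounds"
                        },
                    }
                    for e in self.network.edges
                ],
            }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        network = None
        if payload.get("network") is not None:
            net = payload["network"]
            network = NetworkTruth(
                nodes=list(net["nodes"]),
                categories=dict(net["categories"]),
                edges=[
                    TrueEdge(
                        regulator=e["regulator"],
                        target=e["target"],
                        params=SSystemParams(**e["params"]),
                    )
                    for e in net["edges"]
                ],
                seed=int(net["seed"]),
            )
        return cls(
            seed=int(payload["seed"]),
            network=network,
            planted_srp=payload.get("planted_srp", {}),
            planted_ddct=payload.get("planted_ddct", {}),
            config=payload.get("config", {}),
        )


def generate_network(
    n_proteins: int,
    n_edges: int,
    seed: int,
    use_catalog: bool = True,
) -> NetworkTruth:
    """Sample a sparse acyclic interaction network with planted kinetics.

    Edges are drawn without self-loops and respect a random topological
    order, so every generated network can be simulated sources-first.
    Edge kinetics are drawn from documented ranges: alpha, beta in
    [0.2, 2], |g| in [0.5, 2] with random sign, h = 1. Protein identities
    and functional categories come from the packaged spot catalog when
    ``use_catalog`` is set (limiting n_proteins to 39).
    """
    max_edges = n_proteins * (n_proteins - 1) // 2
    if n_proteins < 2:
        raise ValueError("need at least two proteins")
    if not 0 < n_edges <= max_edges:
        raise ValueError(
            f"cannot place {n_edges} acyclic edges among {n_proteins} "
            f"proteins (max {max_edges})"
        )
    rng = np.random.default_rng(seed)
    if use_catalog:
        catalog = load_spot_catalog()
        if n_proteins > len(catalog):
            raise ValueError(
                f"catalog provides {len(catalog)} proteins, "
                f"{n_proteins} requested"
            )
        idx = rng.choice(len(catalog), size=n_proteins, replace=False)
        rows = catalog.iloc[sorted(idx)]
        nodes = [f"spot{r.spot_id}" for r in rows.itertuples(index=False)]
        categories = {
            f"spot{r.spot_id}": r.category
            for r in rows.itertuples(index=False)
        }
    else:
        nodes = [f"P{i + 1:02d}" for i in range(n_proteins)]
        categories = {n: "other" for n in nodes}

    order = rng.permutation(n_proteins)
    pairs = [
        (i, j)
        for i in range(n_proteins)
        for j in range(n_proteins)
        if order[i] < order[j]
    ]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    edges = []
    for k in sorted(chosen):
        i, j = pairs[k]
        params = SSystemParams(
            alpha=float(rng.uniform(0.2, 2.0)),
            beta=float(rng.uniform(0.2, 2.0)),
            g=float(rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])),
            h=1.0,
        )
        edges.append(TrueEdge(nodes[i], nodes[j], params))
    return NetworkTruth(
        nodes=nodes, categories=categories, edges=edges, seed=int(seed)
    )


@dataclass(frozen=True)
class SourceDriver:
    """Exogenous stress transient driving one source protein.

    The profile is a gamma-shaped pulse on a baseline,
    ``a * (1 + m * (t/tau)**2 * exp(2*(1 - t/tau)))``, peaking at ``tau``
    days with relative amplitude ``m``; ``inverted`` turns the pulse into a
    transient depletion (baseline divided by the same factor). Transient
    rise-then-relax kinetics are what make time-shifted downstream
    responses attributable to their actual driver: a monotone profile can
    be mimicked by regulator-free relaxation, a timed pulse cannot.
    """

    baseline: float
    amplitude: float
    peak_day: float
    inverted: bool = False

    def _bump(self, t: float) -> float:
        z = t / self.peak_day
        return z**2 * np.exp(2.0 * (1.0 - z))

    def value(self, t: float) -> float:
        v = 1.0 + self.amplitude * self._bump(t)
        return self.baseline / v if self.inverted else self.baseline * v

    def derivative(self, t: float) -> float:
        z = t / self.peak_day
        dbump = (2.0 * t / self.peak_day**2) * (1.0 - z) * np.exp(
            2.0 * (1.0 - z)
        )
        if self.inverted:
            v = 1.0 + self.amplitude * self._bump(t)
            return -self.baseline * self.amplitude * dbump / v**2
        return self.baseline * self.amplitude * dbump


def _source_drivers(network: NetworkTruth, rng: np.random.Generator):
    """Sample a stress transient for every source node.

    Baselines in [0.8, 1.5], pulse amplitudes in [0.8, 2.5], peak times in
    [4, 16] days, with a 30% chance of an inverted (depletion) transient.
    """
    drivers = {}
    for node in network.sources():
        drivers[node] = SourceDriver(
            baseline=float(rng.uniform(0.8, 1.5)),
            amplitude=float(rng.uniform(0.8, 2.5)),
            peak_day=float(rng.uniform(4.0, 16.0)),
            inverted=bool(rng.random() < 0.3),
        )
    return drivers


def simulate_timecourse(
    network: NetworkTruth,
    times: np.ndarray | None = None,
    noise_cv: float = 0.02,
    seed: int = 0,
    condition_label: str = "WS+HS",
) -> list[Trajectory]:
    """Integrate the coupled planted dynamics and sample noisy profiles.

    Source nodes follow their exogenous stress transients; every downstream
    node obeys summed power-law production over its regulators minus
    first-order decay (with a single regulator this is exactly the pairwise
    model). The full system is integrated jointly, then multiplicative
    log-normal noise with coefficient of variation ``noise_cv`` is applied
    (mean-preserving, so averaging over noise draws recovers the noiseless
    course).

    Structural randomness (source transients, initial abundances) derives
    from the network's own seed; the ``seed`` argument controls only the
    measurement noise, so varying it explores noise realizations of one
    fixed dynamical system.
    """
    if times is None:
        times = default_times()
    times = np.asarray(times, dtype=float)
    in_edges: dict[str, list[TrueEdge]] = {}
    for e in network.edges:
        in_edges.setdefault(e.target, []).append(e)
    sources = set(network.sources())
    if not sources:
        raise ValueError("network has a cycle: no source node to drive it")
    # reject cycles among non-source nodes
    seen: set[str] = set(sources)
    frontier = True
    while frontier:
        frontier = False
        for node in network.nodes:
            if node in seen:
                continue
            if all(e.regulator in seen for e in in_edges.get(node, [])):
                seen.add(node)
                frontier = True
    if seen != set(network.nodes):
        raise ValueError(
            f"cyclic dependency without a source driver: "
            f"{sorted(set(network.nodes) - seen)}"
        )

    struct_rng = np.random.default_rng(network.seed)
    drivers = _source_drivers(network, struct_rng)
    index = {n: i for i, n in enumerate(network.nodes)}
    eps = 1e-6

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        dx = np.zeros_like(x)
        for node, i in index.items():
            if node in drivers:
                dx[i] = drivers[node].derivative(t)
            else:
                edges = in_edges[node]
                xt = max(x[i], eps)
                production = sum(
                    e.params.alpha * max(x[index[e.regulator]], eps) ** e.params.g
                    for e in edges
                )
                beta = float(np.mean([e.params.beta for e in edges]))
                dx[i] = production - beta * xt ** edges[0].params.h
        return dx

    x0 = np.empty(len(network.nodes))
    for node, i in index.items():
        if node in drivers:
            x0[i] = drivers[node].value(times[0])
        else:
            x0[i] = float(struct_rng.uniform(0.5, 1.5))

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        x0,
        method="LSODA",
        t_eval=times,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"timecourse integration failed: {sol.message}")
    values = np.clip(sol.y, eps, None)

    if noise_cv > 0:
        noise_rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        factors = np.exp(
            noise_rng.normal(0.0, sigma, size=values.shape) - sigma**2 / 2
        )
        values = values * factors

    return [
        Trajectory(
            protein_id=node,
            times=times,
            values=values[index[node]],
            condition_label=condition_label,
        )
        for node in network.nodes
    ]


def generate_spot_table(
    seed: int,
    n_spots: int = 50,
    n_planted: int = 10,
    effect_fold: tuple[float, float] = (1.8, 3.0),
    replicate_cv: float = 0.1,
    replicates: int = 3,
    cultivar: str = "PI-471938",
    use_catalog_ids: bool = False,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Replicated spot-density table with planted stress effects.

    Null spots share one mean density across the four conditions; each
    planted spot receives a single up or down direction applied to a random
    nonempty subset of the three stresses, with a fold effect drawn from
    ``effect_fold`` (comfortably beyond the 1.5 selection threshold).
    Replicate scatter is log-normal with the given coefficient of
    variation. Returns the long-format table and the planted direction map.

    With ``use_catalog_ids`` the spots carry the packaged catalog's
    identities, accessions and categories (n_spots ≤ 39); otherwise ids are
    synthetic and categories are sampled from the catalog's distribution.
    """
    if n_planted > n_spots:
        raise ValueError("cannot plant more spots than exist")
    rng = np.random.default_rng(seed)
    catalog = load_spot_catalog()
    if use_catalog_ids:
        if n_spots > len(catalog):
            raise ValueError(
                f"catalog provides {len(catalog)} spots, {n_spots} requested"
            )
        rows_cat = catalog.iloc[:n_spots]
        spot_ids = [f"spot{r.spot_id}" for r in rows_cat.itertuples(index=False)]
        accessions = dict(zip(spot_ids, rows_cat["accession"]))
        categories = rows_cat["category"].to_numpy()
    else:
        spot_ids = [f"S{i + 1:03d}" for i in range(n_spots)]
        accessions = {s: f"SYN-{s}" for s in spot_ids}
        cat_values = catalog["category"].to_numpy()
        categories = rng.choice(cat_values, size=n_spots, replace=True)
    base = rng.uniform(500.0, 5000.0, size=n_spots)
    planted_idx = rng.choice(n_spots, size=n_planted, replace=False)
    sigma = np.sqrt(np.log1p(replicate_cv**2))

    planted: dict[str, dict[str, str]] = {}
    rows = []
    for s, spot in enumerate(spot_ids):
        means = {c: base[s] for c in CONDITIONS}
        directions = {stress: UNCHANGED for stress in STRESSES}
        if s in planted_idx:
            direction = UP if rng.random() < 0.5 else DOWN
            n_hit = int(rng.integers(1, len(STRESSES) + 1))
            hit = rng.choice(len(STRESSES), size=n_hit, replace=False)
            for k in hit:
                stress = STRESSES[k]
                fold = float(rng.uniform(*effect_fold))
                if direction == DOWN:
                    fold = 1.0 / fold
                means[stress] = base[s] * fold
                directions[stress] = direction
            planted[spot] = directions
        for cond in CONDITIONS:
            noise = np.exp(
                rng.normal(0.0, sigma, size=replicates) - sigma**2 / 2
            )
            for r in range(replicates):
                rows.append(
                    {
                        "spot_id": spot,
                        "accession": accessions[spot],
                        "category": categories[s],
                        "cultivar": cultivar,
                        "condition": cond,
                        "replicate": r + 1,
                        "density": means[cond] * noise[r],
                    }
                )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        seed=int(seed),
        planted_srp=planted,
        config={
            "n_spots": n_spots,
            "n_planted": n_planted,
            "effect_fold": list(effect_fold),
            "replicate_cv": replicate_cv,
            "replicates": replicates,
            "cultivar": cultivar,
            "use_catalog_ids": use_catalog_ids,
        },
    )
    return table, truth


def generate_qpcr(
    seed: int,
    genes: tuple[str, ...] = QPCR_GENES,
    planted_ddct: dict[str, dict[str, float]] | None = None,
    ct_noise_sd: float = 0.15,
    replicates: int = 5,
    reference_ct: float = 20.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Ct table with planted ΔΔCt shifts against a constant-mean reference.

    Each gene gets a baseline ΔCt (expression level relative to actin);
    stress treatments shift the target Ct by the planted ΔΔCt. When
    ``planted_ddct`` is omitted, shifts are drawn uniformly from [−2, 2]
    (up to 4-fold either way) for the stresses and 0 for the control.
    With ``ct_noise_sd = 0`` the 2^−ΔΔCt estimate is exact.
    """
    rng = np.random.default_rng(seed)
    if planted_ddct is None:
        planted_ddct = {
            gene: {
                treatment: (
                    0.0
                    if treatment == CONTROL
                    else float(np.round(rng.uniform(-2.0, 2.0), 3))
                )
                for treatment in CONDITIONS
            }
            for gene in genes
        }
    else:
        for gene in genes:
            missing = set(CONDITIONS) - set(planted_ddct.get(gene, {}))
            if missing:
                raise ValueError(
                    f"planted ΔΔCt incomplete for {gene}: missing {missing}"
                )

    base_dct = {gene: float(rng.uniform(2.0, 8.0)) for gene in genes}
    rows = []
    for gene in genes:
        for treatment in CONDITIONS:
            shift = planted_ddct[gene][treatment]
            for r in range(replicates):
                ref = reference_ct + rng.normal(0.0, ct_noise_sd)
                tgt = (
                    reference_ct
                    + base_dct[gene]
                    + shift
                    + rng.normal(0.0, ct_noise_sd)
                )
                rows.append(
                    {
                        "gene": gene,
                        "treatment": treatment,
                        "replicate": r + 1,
                        "ct_target": tgt,
                        "ct_reference": ref,
                    }
                )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        seed=int(seed),
        planted_ddct=planted_ddct,
        config={
            "ct_noise_sd": ct_noise_sd,
            "replicates": replicates,
            "reference_ct": reference_ct,
        },
    )
    return table, truth


def generate_enzyme_table(
    seed: int,
    enzymes: tuple[str, ...] = ("SOD", "POD", "CAT", "APX", "GR"),
    replicates: int = 3,
    replicate_cv: float = 0.08,
    nd_enzyme: str = "GR",
    nd_condition: str = "WS+HS",
) -> pd.DataFrame:
    """Enzyme activity table with planted fold effects over control.

    One enzyme/condition combination (glutathione reductase under combined
    stress by default) is emitted as the not-detected sentinel to exercise
    the flagged zero-fold path.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(replicate_cv**2))
    rows = []
    for enzyme in enzymes:
        control_level = float(rng.uniform(5.0, 50.0))
        for cond in CONDITIONS:
            if cond == CONTROL:
                level = control_level
            else:
                level = control_level * float(rng.uniform(0.4, 2.5))
            for r in range(replicates):
                if enzyme == nd_enzyme and cond == nd_condition:
                    activity: float | str = "ND"
                else:
                    activity = level * float(
                        np.exp(rng.normal(0.0, sigma) - sigma**2 / 2)
                    )
                rows.append(
                    {
                        "enzyme": enzyme,
                        "condition": cond,
                        "replicate": r + 1,
                        "activity": activity,
                    }
                )
    return pd.DataFrame(rows)
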