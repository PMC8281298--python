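"""Synthetic methylation study generator.

Emulates a 4-stage differentiation time course profiled on a two-chemistry
bead array: a beta-value matrix with a planted fraction of
trajectory-associated loci drawn from nine shape modules, matched
methylated/unmethylated intensities with planted QC-failing samples, a probe
annotation table with tiltable category odds, a sparse linear epigenetic
clock that is exact on the noiseless data, and a directed gene network with a
planted strongly connected component.  Every generator is deterministic
under a fixed seed; one global seed drives independent child seeds per
component.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from methyltraj.clocks import ClockModel

# ---------------------------------------------------------------------------
# trajectory shape modules
# ---------------------------------------------------------------------------


def _linear_up(t: np.ndarray) -> np.ndarray:
    return np.asarray(t, dtype=float)


def _linear_down(t: np.ndarray) -> np.ndarray:
    return 1.0 - np.asarray(t, dtype=float)


def _early_drop(t: np.ndarray, rate: float = 6.0) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return (np.exp(-rate * t) - np.exp(-rate)) / (1.0 - np.exp(-rate))


def _late_rise(t: np.ndarray, rate: float = 6.0) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return (np.exp(rate * (t - 1.0)) - np.exp(-rate)) / (1.0 - np.exp(-rate))


def _sigmoid_up(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    lo, hi = expit(-5.0), expit(5.0)
    return (expit(10.0 * (t - 0.5)) - lo) / (hi - lo)


def _sigmoid_down(t: np.ndarray) -> np.ndarray:
    return 1.0 - _sigmoid_up(t)


def _early_drop_steep(t: np.ndarray) -> np.ndarray:
    # loses most of its methylation between the first two stages
    return _early_drop(t, rate=12.0)


def _transient_peak(t: np.ndarray) -> np.ndarray:
    return np.sin(np.pi * np.asarray(t, dtype=float))


def _transient_dip(t: np.ndarray) -> np.ndarray:
    return 1.0 - _transient_peak(t)


#: The nine trajectory templates, all mapping [0, 1] -> [0, 1].
MODULE_SHAPES: List[Callable[[np.ndarray], np.ndarray]] = [
    _linear_up,        # M1
    _linear_down,      # M2
    _early_drop,       # M3
    _late_rise,        # M4
    _sigmoid_up,       # M5
    _sigmoid_down,     # M6
    _early_drop_steep, # M7
    _transient_peak,   # M8
    _transient_dip,    # M9
]

#: Default stage labels / collection days for a 4-stage neuronal course.
DEFAULT_STAGES = ["iPSC", "NPC", "Neuron_d37", "Neuron_d58"]
DEFAULT_DAYS = [0, 16, 37, 58]

REGION_GROUPS = ["TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic"]
REGION_BASE_PROBS = [0.13, 0.10, 0.09, 0.05, 0.36, 0.04, 0.23]
CGI_RELATIONS = ["island", "shore", "shelf", "open_sea"]
CGI_BASE_PROBS = [0.31, 0.23, 0.10, 0.36]

EFFECT_LABELS = ["activation", "inhibition", "unspecified"]


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults encode the study design the generator emulates: 4 stages x 4
    technical replicates (16 samples), 2 samples planted to fail intensity QC,
    5% of probes carrying a genuine pseudotime dependence spread over the 9
    shape modules, and beta-scale noise of sd 0.03.
    """

    n_probes: int = 10_000
    n_stages: int = 4
    replicates_per_stage: int = 4
    frac_associated: float = 0.05
    noise_sd: float = 0.03
    mean_total_intensity: float = 5000.0
    n_failing_samples: int = 2
    stage_jitter: float = 0.01
    amplitude_range: tuple = (0.3, 0.6)
    module_shapes: Sequence[Callable] = field(default_factory=lambda: list(MODULE_SHAPES))
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_stages * self.replicates_per_stage

    def validate(self) -> None:
        if self.n_probes < 20:
            raise InvalidConfigError("n_probes must be >= 20")
        if self.n_samples < 2:
            raise InvalidConfigError("need at least 2 samples")
        if not (0.0 <= self.frac_associated < 1.0):
            raise InvalidConfigError("frac_associated must be in [0, 1)")
        n_assoc = int(round(self.frac_associated * self.n_probes))
        if self.frac_associated > 0 and n_assoc < len(self.module_shapes):
            raise InvalidConfigError(
                "frac_associated * n_probes must cover every shape module "
                f"(need >= {len(self.module_shapes)}, got {n_assoc})"
            )
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if self.n_failing_samples >= self.n_samples:
            raise InvalidConfigError("cannot fail all samples")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study, used by recovery tests.

    ``locus_base``/``locus_amplitude`` record, per associated locus, the
    parameters of its noiseless mean curve
    ``mu(t) = base + amplitude * (shape(t) - 0.5)`` so downstream generators
    (e.g. the planted clock) can reconstruct the noiseless signal.
    """

    true_time: Dict[str, float]
    associated_loci: List[str]
    module_label: Dict[str, int]
    locus_base: Dict[str, float]
    locus_amplitude: Dict[str, float]
    true_delta_end: Dict[str, float]
    failing_samples: List[str]
    planted_scc_nodes: List[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent child generator ``stream`` of the global ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def default_probe_types(probe_ids: Sequence[str]) -> pd.Series:
    """Deterministic chemistry assignment: ~30% type I, interleaved."""
    types = np.where(np.arange(len(probe_ids)) % 10 < 3, "I", "II")
    return pd.Series(types, index=list(probe_ids), name="probe_type")


def stage_labels(n_stages: int) -> List[str]:
    if n_stages == len(DEFAULT_STAGES):
        return list(DEFAULT_STAGES)
    return [f"stage{k + 1}" for k in range(n_stages)]


def stage_days(n_stages: int) -> List[int]:
    if n_stages == len(DEFAULT_DAYS):
        return list(DEFAULT_DAYS)
    return list(range(n_stages))


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------


def simulate_beta_dataset(config: SimulationConfig):
    """Simulate (beta matrix, sample sheet, truth) for the configured design.

    Associated loci follow their module template of the latent time; noise is
    added on the logit scale and inverse-transformed, so emitted beta values
    respect [0, 1] without clipping.  Non-associated loci are flat (a bimodal
    baseline typical of methylation arrays) plus the same noise.
    """
    config.validate()
    rng = _child_rng(config.seed, 0)

    labels = stage_labels(config.n_stages)
    days = stage_days(config.n_stages)
    sample_ids, stages, sample_days, true_time = [], [], [], []
    for s in range(config.n_stages):
        t_stage = s / (config.n_stages - 1) if config.n_stages > 1 else 0.0
        for r in range(config.replicates_per_stage):
            sample_ids.append(f"{labels[s]}_R{r + 1}")
            stages.append(labels[s])
            sample_days.append(days[s])
            true_time.append(t_stage)
    true_time = np.asarray(true_time, dtype=float)
    if config.stage_jitter > 0:
        true_time = true_time + config.stage_jitter * rng.standard_normal(len(true_time))
        true_time = np.clip(true_time, 0.0, 1.0)

    samples = pd.DataFrame(
        {"sample_id": sample_ids, "stage": stages, "day": sample_days}
    ).set_index("sample_id")

    probe_ids = [f"cg{i:08d}" for i in range(config.n_probes)]
    n_assoc = int(round(config.frac_associated * config.n_probes))
    assoc_idx = rng.choice(config.n_probes, size=n_assoc, replace=False)
    assoc_idx.sort()

    n_mod = len(config.module_shapes)
    modules = (np.arange(n_assoc) % n_mod) + 1
    lo, hi = config.amplitude_range
    amplitude = rng.uniform(lo, hi, size=n_assoc)
    base = rng.uniform(0.35, 0.65, size=n_assoc)

    # flat baseline for the null loci: bimodal, as on real arrays
    comp = rng.choice(3, size=config.n_probes, p=[0.4, 0.4, 0.2])
    flat = np.where(
        comp == 0,
        rng.beta(2, 10, size=config.n_probes),
        np.where(comp == 1, rng.beta(10, 2, size=config.n_probes), rng.beta(5, 5, size=config.n_probes)),
    )
    flat = np.clip(flat, 0.02, 0.98)

    mu = np.tile(flat[:, None], (1, len(sample_ids)))
    for j, (idx, m) in enumerate(zip(assoc_idx, modules)):
        shape = config.module_shapes[m - 1]
        mu[idx, :] = base[j] + amplitude[j] * (np.asarray(shape(true_time)) - 0.5)
    mu = np.clip(mu, 1e-3, 1.0 - 1e-3)

    if config.noise_sd > 0:
        # delta method: logit-scale sd that yields ~noise_sd on the beta scale
        sd_logit = config.noise_sd / (mu * (1.0 - mu))
        beta = expit(logit(mu) + sd_logit * rng.standard_normal(mu.shape))
    else:
        beta = mu.copy()

    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)
    beta_df.index.name = "probe_id"

    assoc_ids = [probe_ids[i] for i in assoc_idx]
    shape_delta = {
        pid: float(amplitude[j] * (config.module_shapes[modules[j] - 1](np.array([1.0]))[0]
                                   - config.module_shapes[modules[j] - 1](np.array([0.0]))[0]))
        for j, pid in enumerate(assoc_ids)
    }
    failing = sample_ids[: config.n_failing_samples]
    truth = SyntheticTruth(
        true_time={sid: float(t) for sid, t in zip(sample_ids, true_time)},
        associated_loci=assoc_ids,
        module_label={pid: int(m) for pid, m in zip(assoc_ids, modules)},
        locus_base={pid: float(b) for pid, b in zip(assoc_ids, base)},
        locus_amplitude={pid: float(a) for pid, a in zip(assoc_ids, amplitude)},
        true_delta_end=shape_delta,
        failing_samples=list(failing),
    )
    return beta_df, samples, truth


def noiseless_mean_curve(truth: SyntheticTruth, probe_id: str,
                         t: np.ndarray,
                         module_shapes: Sequence[Callable] = MODULE_SHAPES) -> np.ndarray:
    """Noiseless mean beta of an associated locus at latent times ``t``."""
    m = truth.module_label[probe_id]
    shape = module_shapes[m - 1]
    return truth.locus_base[probe_id] + truth.locus_amplitude[probe_id] * (
        np.asarray(shape(np.asarray(t, dtype=float))) - 0.5
    )


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------


def simulate_intensities(beta: pd.DataFrame, config: SimulationConfig,
                         truth: Optional[SyntheticTruth] = None,
                         intensity_cv: float = 0.15,
                         type1_offset: float = 200.0,
                         failing_scale: float = 0.04):
    """Simulate M/U intensities, detection p-values and bead counts.

    ``M = beta * T + offset(type)``, ``U = (1 - beta) * T + offset(type)``
    with per-entry total intensity ``T`` drawn around
    ``config.mean_total_intensity``.  Samples listed in
    ``truth.failing_samples`` get their intensities scaled down by
    ``failing_scale`` and their detection p-values inflated so that both the
    median-intensity check and the p-filter flag exactly those samples.
    """
    vals = beta.to_numpy()
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("beta values must lie in [0, 1]")
    rng = _child_rng(config.seed, 1)
    n_probes, n_samples = vals.shape

    if intensity_cv > 0:
        shape_k = 1.0 / intensity_cv**2
        total = rng.gamma(shape_k, config.mean_total_intensity / shape_k, size=vals.shape)
    else:
        total = np.full(vals.shape, config.mean_total_intensity)

    probe_type = default_probe_types(beta.index)
    offset = np.where(probe_type.to_numpy() == "I", type1_offset, 0.0)[:, None]
    meth = vals * total + offset
    unmeth = (1.0 - vals) * total + offset

    detp = rng.beta(1, 2000, size=vals.shape)
    beadcount = rng.poisson(14, size=vals.shape) + 4

    failing = list(truth.failing_samples) if truth is not None else []
    for sid in failing:
        j = beta.columns.get_loc(sid)
        meth[:, j] *= failing_scale
        unmeth[:, j] *= failing_scale
        bad = rng.random(n_probes) < 0.05
        detp[bad, j] = rng.uniform(0.06, 0.5, size=int(bad.sum()))

    def _df(arr):
        out = pd.DataFrame(arr, index=beta.index, columns=beta.columns)
        out.index.name = "probe_id"
        return out

    return _df(meth), _df(unmeth), _df(detp), _df(beadcount)


def recompute_beta(meth: pd.DataFrame, unmeth: pd.DataFrame, offset: float = 100.0) -> pd.DataFrame:
    """Beta from intensities with the conventional additive offset."""
    return meth / (meth + unmeth + offset)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def simulate_annotation(config: SimulationConfig, truth: SyntheticTruth,
                        region_tilt: Optional[Dict[str, float]] = None,
                        cgi_tilt: Optional[Dict[str, float]] = None,
                        n_genes: Optional[int] = None,
                        snp_rate: float = 0.03,
                        crossreactive_rate: float = 0.03) -> pd.DataFrame:
    """Simulate a probe annotation table with tiltable category odds.

    For non-associated probes categories are drawn from the base
    probabilities; for associated probes the odds of each tilted category are
    multiplied by its tilt factor, so a single-category tilt ``theta`` makes
    the population Fisher odds ratio of that category (associated vs rest)
    exactly ``theta``.
    """
    rng = _child_rng(config.seed, 2)
    probe_ids = [f"cg{i:08d}" for i in range(config.n_probes)]
    assoc = np.zeros(config.n_probes, dtype=bool)
    assoc_pos = {pid: True for pid in truth.associated_loci}
    for i, pid in enumerate(probe_ids):
        if pid in assoc_pos:
            assoc[i] = True

    def _draw(categories, base_probs, tilt):
        base = np.asarray(base_probs, dtype=float)
        base = base / base.sum()
        out = np.empty(config.n_probes, dtype=object)
        null_idx = np.flatnonzero(~assoc)
        out[null_idx] = rng.choice(categories, size=null_idx.size, p=base)
        tilted = base.copy()
        if tilt:
            for cat, odds in tilt.items():
                k = categories.index(cat)
                # odds multiplication: p/(1-p) -> odds * p/(1-p)
                tilted[k] = base[k] * odds / (base[k] * odds + (1 - base[k]))
                rest = [j for j in range(len(categories)) if j != k]
                scale = (1 - tilted[k]) / base[rest].sum()
                for j in rest:
                    tilted[j] = base[j] * scale
        tilted = tilted / tilted.sum()
        a_idx = np.flatnonzero(assoc)
        out[a_idx] = rng.choice(categories, size=a_idx.size, p=tilted)
        return out

    region = _draw(REGION_GROUPS, REGION_BASE_PROBS, region_tilt)
    cgi = _draw(CGI_RELATIONS, CGI_BASE_PROBS, cgi_tilt)

    if n_genes is None:
        n_genes = max(50, config.n_probes // 10)
    gene_names = np.array([f"G{i + 1:04d}" for i in range(n_genes)])
    # nonuniform gene weights -> uneven probes-per-gene (the bias the
    # gene-set test corrects for)
    w = 1.0 / np.arange(1, n_genes + 1) ** 0.5
    w /= w.sum()
    genes = np.empty(config.n_probes, dtype=object)
    g1 = rng.choice(n_genes, size=config.n_probes, p=w)
    second = rng.random(config.n_probes) < 0.10
    g2 = rng.choice(n_genes, size=config.n_probes, p=w)
    for i in range(config.n_probes):
        if region[i] == "intergenic":
            genes[i] = ""
        elif second[i] and g2[i] != g1[i]:
            genes[i] = f"{gene_names[g1[i]]};{gene_names[g2[i]]}"
        else:
            genes[i] = gene_names[g1[i]]

    snp = rng.random(config.n_probes) < snp_rate
    xr = rng.random(config.n_probes) < crossreactive_rate
    chrom = rng.integers(1, 23, size=config.n_probes)
    pos = rng.integers(10_000, 200_000_000, size=config.n_probes)

    ann = pd.DataFrame(
        {
            "gene_symbols": genes,
            "region_group": region,
            "cgi_relation": cgi,
            "snp_flag": snp,
            "crossreactive_flag": xr,
            "chromosome": [f"chr{c}" for c in chrom],
            "position": pos,
            "probe_type": default_probe_types(probe_ids).to_numpy(),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ann


# ---------------------------------------------------------------------------
# directed network
# ---------------------------------------------------------------------------


def simulate_network(n_genes: int, scc_size: int, extra_edges: int = 0,
                     seed: int = 0, periphery_density: float = 1.2):
    """Simulate a directed edge list with exactly one planted nontrivial SCC.

    The SCC is a directed cycle over ``scc_size`` genes plus ``extra_edges``
    chords; the remaining genes form an acyclic periphery wired so that no
    path re-enters its origin (upstream half feeds the SCC, the SCC feeds the
    downstream half).  ``scc_size = 0`` disables the planted component and
    yields a pure DAG.

    Returns ``(edges, scc_nodes)`` where ``edges`` is a DataFrame with
    columns source/target/effect.
    """
    if scc_size == 1 or scc_size < 0:
        raise InvalidConfigError("scc_size must be 0 (disabled) or >= 2")
    if scc_size > n_genes:
        raise InvalidConfigError("scc_size cannot exceed n_genes")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    scc_nodes = genes[:scc_size]
    edges = set()
    if scc_size >= 2:
        for i in range(scc_size):
            edges.add((scc_nodes[i], scc_nodes[(i + 1) % scc_size]))
        tries = 0
        while len(edges) < scc_size + extra_edges and tries < 50 * (extra_edges + 1):
            a, b = rng.integers(0, scc_size, size=2)
            tries += 1
            if a != b:
                edges.add((scc_nodes[a], scc_nodes[b]))

    periphery = genes[scc_size:]
    if periphery:
        half = len(periphery) // 2
        upstream, downstream = periphery[:half], periphery[half:]
        n_extra = int(periphery_density * len(periphery))
        for _ in range(n_extra):
            kind = rng.integers(0, 4)
            if kind == 0 and len(upstream) >= 2:
                i, j = sorted(rng.choice(len(upstream), size=2, replace=False))
                edges.add((upstream[i], upstream[j]))
            elif kind == 1 and upstream and scc_nodes:
                edges.add((upstream[rng.integers(len(upstream))],
                           scc_nodes[rng.integers(len(scc_nodes))]))
            elif kind == 2 and downstream and scc_nodes:
                edges.add((scc_nodes[rng.integers(len(scc_nodes))],
                           downstream[rng.integers(len(downstream))]))
            elif len(downstream) >= 2:
                i, j = sorted(rng.choice(len(downstream), size=2, replace=False))
                edges.add((downstream[i], downstream[j]))
        # keep the periphery reachable even at low density
        for k in range(len(upstream) - 1):
            edges.add((upstream[k], upstream[k + 1]))
        for k in range(len(downstream) - 1):
            edges.add((downstream[k], downstream[k + 1]))
        if upstream and scc_nodes:
            edges.add((upstream[-1], scc_nodes[0]))
        if downstream and scc_nodes:
            edges.add((scc_nodes[0], downstream[0]))

    edge_list = sorted(edges)
    effects = [EFFECT_LABELS[rng.integers(0, 3)] for _ in edge_list]
    df = pd.DataFrame(
        {"source": [e[0] for e in edge_list],
         "target": [e[1] for e in edge_list],
         "effect": effects}
    )
    return df, set(scc_nodes)


def reference_like_network():
    """Deterministic synthetic stand-in for a curated regulatory network.

    Synthetic construction (no external database is queried): a 398-gene,
    622-interaction directed network whose unique nontrivial strongly
    connected component has 60 genes and 158 interactions, with hub gene
    ``STAT3`` having in-degree 7 and out-degree 20 — the headline topology of
    the regulatory subnetwork this package's network stage is designed to
    characterize.

    Returns ``(edges, scc_nodes)``.
    """
    scc = ["STAT3"] + [f"SG{i:02d}" for i in range(1, 60)]
    edges: List[tuple] = []
    seen = set()

    def add(u, v):
        if u != v and (u, v) not in seen:
            seen.add((u, v))
            edges.append((u, v))

    # 60-cycle guarantees strong connectivity
    for i in range(60):
        add(scc[i], scc[(i + 1) % 60])
    # hub out-edges: 20 targets spaced around the cycle (SG01 already via it)
    for i in range(1, 59, 3):
        add("STAT3", f"SG{i:02d}")
    # hub in-edges: SG59 via the cycle, 3 reciprocal, 3 more -> in-degree 7
    for i in [1, 4, 7, 2, 5, 8]:
        add(f"SG{i:02d}", "STAT3")
    # 73 chords among the non-hub SCC genes (cycle steps 14 then 10), chosen
    # so the hub's neighborhood stays sparse like a curated hub's
    n_before = len(edges)
    for step in (14, 10):
        for a in range(1, 60):
            if len(edges) - n_before >= 73:
                break
            b = (a - 1 + step) % 59 + 1
            add(f"SG{a:02d}", f"SG{b:02d}")
    assert len(edges) == 158

    periphery = [f"PG{i:03d}" for i in range(1, 339)]
    upstream, downstream = periphery[:169], periphery[169:]
    # two 169-node chains (168 edges each) keep the periphery acyclic
    for chain in (upstream, downstream):
        for k in range(len(chain) - 1):
            edges.append((chain[k], chain[k + 1]))
    # 64 upstream->SCC and 64 SCC->downstream links, avoiding the hub
    for i in range(64):
        edges.append((upstream[i % len(upstream)], f"SG{i % 59 + 1:02d}"))
        edges.append((f"SG{(i + 17) % 59 + 1:02d}", downstream[i % len(downstream)]))
    seen = set()
    uniq = []
    for e in edges:
        if e not in seen:
            seen.add(e)
            uniq.append(e)
    assert len(uniq) == 622, len(uniq)
    df = pd.DataFrame(
        {"source": [e[0] for e in uniq],
         "target": [e[1] for e in uniq],
         "effect": [EFFECT_LABELS[k % 3] for k in range(len(uniq))]}
    )
    return df, set(scc)


# ---------------------------------------------------------------------------
# planted clock
# ---------------------------------------------------------------------------


def simulate_clock(probe_ids: Sequence[str], truth: SyntheticTruth,
                   n_clock_cpgs: int = 20, output_unit: str = "days_post_conception",
                   transform: str = "identity", seed: int = 0,
                   age_range: tuple = (48.0, 97.0)) -> ClockModel:
    """Plant a sparse linear clock that is exact on the noiseless data.

    The clock CpGs are drawn from the linearly increasing shape module, whose
    noiseless mean is ``base + amplitude * (t - 0.5)``; weights are chosen so
    the linear predictor equals the target increasing age function of the
    latent time exactly.  For ``transform='horvath_antitrafo'`` the target is
    linear on the pre-transform scale instead (crossing the piecewise knot),
    so exact recovery still holds after the transform.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(4,)))
    probe_set = set(probe_ids)
    linear_up_loci = [
        pid for pid in truth.associated_loci
        if truth.module_label[pid] == 1 and pid in probe_set
    ]
    if not linear_up_loci:
        raise InvalidConfigError("no linearly increasing associated loci to build a clock from")
    if n_clock_cpgs > len(probe_set):
        raise InvalidConfigError("n_clock_cpgs exceeds the probe universe")
    k = min(n_clock_cpgs, len(linear_up_loci))
    chosen = list(rng.choice(linear_up_loci, size=k, replace=False))

    if transform == "identity":
        a0, a1 = age_range[0], age_range[1] - age_range[0]  # age = a0 + a1 * t
    elif transform == "horvath_antitrafo":
        a0, a1 = -1.0, 2.0  # pre-transform m = -1 + 2 t, crosses the knot at 0
    else:
        raise InvalidConfigError(f"unknown transform {transform!r}")

    # mu_l(t) = base_l + amp_l (t - 0.5)  =>  sum w_l mu_l = a0 + a1 t requires
    # sum w_l amp_l = a1 with intercept absorbing the rest; spread evenly.
    weights = {pid: a1 / (k * truth.locus_amplitude[pid]) for pid in chosen}
    intercept = a0 - sum(
        w * (truth.locus_base[pid] - 0.5 * truth.locus_amplitude[pid])
        for pid, w in weights.items()
    )
    return ClockModel(
        name=f"synthetic_{'fetal' if transform == 'identity' else 'pan_tissue'}",
        coefficients=weights,
        intercept=float(intercept),
        transform=transform,
        output_unit=output_unit,
    )


# ---------------------------------------------------------------------------
# one-call study bundle
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """Everything one simulated study emits, bundled for the pipeline."""

    config: SimulationConfig
    beta: pd.DataFrame
    samples: pd.DataFrame
    meth: pd.DataFrame
    unmeth: pd.DataFrame
    detp: pd.DataFrame
    beadcount: pd.DataFrame
    annotation: pd.DataFrame
    clock: ClockModel
    network_edges: pd.DataFrame
    truth: SyntheticTruth


def simulate_study(config: SimulationConfig,
                   region_tilt: Optional[Dict[str, float]] = None,
                   cgi_tilt: Optional[Dict[str, float]] = None,
                   n_network_genes: int = 200, scc_size: int = 60,
                   scc_extra_edges: int = 98) -> SyntheticStudy:
    """Simulate a complete study (beta, intensities, annotation, clock, network)."""
    beta, samples, truth = simulate_beta_dataset(config)
    meth, unmeth, detp, bead = simulate_intensities(beta, config, truth)
    ann = simulate_annotation(config, truth, region_tilt=region_tilt, cgi_tilt=cgi_tilt)
    clock = simulate_clock(list(beta.index), truth, seed=config.seed)
    edges, scc_nodes = simulate_network(n_network_genes, scc_size,
                                        extra_edges=scc_extra_edges, seed=config.seed)
    truth.planted_scc_nodes = sorted(scc_nodes)
    return SyntheticStudy(config, beta, samples, meth, unmeth, detp, bead,
                          ann, clock, edges, truth)
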