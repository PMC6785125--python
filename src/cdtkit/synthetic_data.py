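"""Seeded generators for every input the pipeline consumes.

Provides coalescent genealogies under a two-epoch demographic model
(constant ancient size followed by exponential or logistic growth),
HKY+Gamma sequence evolution along those genealogies, clean two-population
split histories, and a synthetic glacial-interglacial temperature record
with a rapid warming phase.  Everything is deterministic given a seed: all
randomness flows from ``numpy.random.default_rng`` streams derived from one
root ``SeedSequence``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .popgen_stats import Alignment
from .substitution import SubstitutionModel
from .trees import Genealogy, MUTATION_UNITS

__all__ = [
    "TwoEpochModel",
    "TemperatureRecord",
    "SplitHistory",
    "simulate_coalescent",
    "simulate_sequences",
    "simulate_split",
    "synth_temperature",
    "make_fixture_set",
]


@dataclass
class TwoEpochModel:
    """Demographic function N(t), t measured backwards from the present.

    An ancient epoch of constant (mutation-scaled) size ``theta_ancient``
    precedes a modern epoch of growth up to ``theta_modern`` at t = 0.  The
    pairwise coalescence rate at time t is 1/N(t), i.e. k lineages coalesce
    at rate k(k-1)/(2 N(t)).

    * ``exponential``: N(t) = theta_modern * exp(-g t) for t < TT and
      theta_ancient beyond, with g fixed by continuity at the transition
      time TT (so theta_ancient = theta_modern gives a constant size).
    * ``logistic``: N(t) = theta_ancient +
      (theta_modern - theta_ancient) / (1 + exp((t - TT)/s)); TT is the
      inflection (half-growth) time and ``logistic_shape`` s the steepness
      (defaults to TT/10).
    """

    kind: str
    theta_modern: float
    theta_ancient: float
    transition_time: float
    logistic_shape: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "logistic"):
            raise ValueError(f"unknown TEM kind {self.kind!r}")
        if min(self.theta_modern, self.theta_ancient, self.transition_time) <= 0:
            raise ValueError("theta_modern, theta_ancient and transition_time must be > 0")
        if self.kind == "logistic" and self.logistic_shape is None:
            self.logistic_shape = self.transition_time / 10.0
        if self.logistic_shape is not None and self.logistic_shape <= 0:
            raise ValueError("logistic_shape must be > 0")

    @property
    def _growth(self) -> float:
        return np.log(self.theta_modern / self.theta_ancient) / self.transition_time

    def size(self, t):
        """N(t); accepts scalars or arrays, t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        if self.kind == "exponential":
            out = np.where(
                t < self.transition_time,
                self.theta_modern * np.exp(-self._growth * np.minimum(t, self.transition_time)),
                self.theta_ancient,
            )
        else:
            x = (t - self.transition_time) / self.logistic_shape
            out = self.theta_ancient + (self.theta_modern - self.theta_ancient) / (
                1.0 + np.exp(np.clip(x, -700, 700))
            )
        return out if out.ndim else float(out)

    def intensity_antiderivative(self, t):
        """A(t) = integral_0^t du / N(u), closed form, vectorized; A(0) = 0."""
        t = np.asarray(t, dtype=float)
        if self.kind == "exponential":
            tt, g = self.transition_time, self._growth
            below = np.minimum(t, tt)
            if g == 0.0:
                a = below / self.theta_modern
            else:
                a = (np.exp(g * below) - 1.0) / (g * self.theta_modern)
            a = a + np.maximum(t - tt, 0.0) / self.theta_ancient
        else:
            s, th1, th2 = self.logistic_shape, self.theta_ancient, self.theta_modern

            def anti(x):
                log_l = np.logaddexp(np.log(th2), np.log(th1) + x)
                return s * (x / th2 + log_l * (1.0 / th1 - 1.0 / th2))

            x = (t - self.transition_time) / s
            x0 = -self.transition_time / s
            a = anti(x) - anti(x0)
        return a if a.ndim else float(a)

    def inverse_size_integral(self, t0: float, t1: float) -> float:
        """Closed-form integral of dt / N(t) over [t0, t1]."""
        if t1 < t0:
            raise ValueError("t1 must be >= t0")
        return float(
            self.intensity_antiderivative(t1) - self.intensity_antiderivative(t0)
        )

    def invert_intensity(self, t0: float, target: float) -> float:
        """Solve integral_{t0}^{t} du/N(u) = target for t (time rescaling)."""
        if target <= 0:
            return t0
        n_max = max(self.theta_modern, self.theta_ancient)
        hi = t0 + target * n_max * 1.0000001 + 1e-300
        f = lambda t: self.inverse_size_integral(t0, t) - target
        return float(brentq(f, t0, hi, xtol=1e-15, rtol=1e-14))


@dataclass
class TemperatureRecord:
    """A proxy temperature-anomaly series on a strictly increasing age grid
    (years before present)."""

    ages: np.ndarray
    temperatures: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.ages.size != self.temperatures.size or self.ages.size < 2:
            raise ValueError("ages and temperatures must have equal length >= 2")
        if np.any(self.ages < 0):
            raise ValueError("ages must be >= 0")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"age_yr_bp": self.ages, "temp_anomaly_c": self.temperatures}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TemperatureRecord":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


@dataclass
class SplitHistory:
    """Two demes with no migration after a clean split.

    ``deme_sizes`` are per-deme TwoEpochModel instances or constant sizes;
    ``ancestral_size`` is the constant size of the merged ancestral deme
    (defaults to deme A's ancient size).
    """

    split_time: float
    deme_sizes: tuple
    sample_sizes: tuple[int, int]
    ancestral_size: float | None = None

    def __post_init__(self) -> None:
        if self.split_time <= 0:
            raise ValueError("split_time must be > 0")
        if len(self.deme_sizes) != 2 or len(self.sample_sizes) != 2:
            raise ValueError("exactly two demes required")
        if min(self.sample_sizes) < 1:
            raise ValueError("each deme needs at least one sampled individual")
        if self.ancestral_size is None:
            d = self.deme_sizes[0]
            self.ancestral_size = d.theta_ancient if isinstance(d, TwoEpochModel) else float(d)


def _as_model(size) -> TwoEpochModel:
    if isinstance(size, TwoEpochModel):
        return size
    return TwoEpochModel("exponential", float(size), float(size), 1.0)


# ---------------------------------------------------------------------------
# coalescent simulation
# ---------------------------------------------------------------------------

def _coalesce(
    lineages: list[int],
    times: np.ndarray,
    parent: np.ndarray,
    model: TwoEpochModel,
    t_start: float,
    t_stop: float | None,
    next_node: int,
    rng: np.random.Generator,
) -> tuple[list[int], float, int]:
    """Run the inhomogeneous coalescent on ``lineages`` from t_start until one
    lineage remains or t_stop is reached; mutates times/parent in place."""
    t = t_start
    while len(lineages) > 1:
        k = len(lineages)
        target = rng.exponential() / (k * (k - 1) / 2.0)
        t_next = model.invert_intensity(t, target)
        if t_stop is not None and t_next > t_stop:
            return lineages, t_stop, next_node
        t = t_next
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        times[next_node] = t
        parent[a] = parent[b] = next_node
        lineages = [x for x in lineages if x not in (a, b)] + [next_node]
        next_node += 1
    return lineages, t, next_node


def simulate_coalescent(
    n_samples: int, model: TwoEpochModel, seed: int, labels: list[str] | None = None
) -> Genealogy:
    """Simulate a genealogy under the two-epoch coalescent by time rescaling.

    Waiting times follow the inhomogeneous rate k(k-1)/(2 N(t)): unit-rate
    exponentials are mapped through the inverse cumulative intensity, whose
    closed form each model kind provides.  Times are mutation-scaled
    (substitutions/site), matching the model's theta units.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    n_nodes = 2 * n_samples - 1
    times = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    _coalesce(list(range(n_samples)), times, parent, model, 0.0, None, n_samples, rng)
    if labels is None:
        labels = [f"seq{i:03d}" for i in range(n_samples)]
    return Genealogy(parent, times, labels, time_units=MUTATION_UNITS)


def simulate_sequences(
    genealogy: Genealogy, subst: SubstitutionModel, length: int, seed: int
) -> Alignment:
    """Evolve sequences site-independently down the genealogy under
    HKY(+Gamma).  The root draws from the stationary base frequencies; each
    site keeps one Gamma rate category along the whole tree."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if genealogy.time_units != MUTATION_UNITS:
        raise ValueError("genealogy must be timed in substitutions/site")
    bl = genealogy.branch_lengths()
    if np.any(
        genealogy.times[genealogy.parent[genealogy.parent >= 0]]
        < genealogy.times[np.flatnonzero(genealogy.parent >= 0)]
    ):
        raise ValueError("negative branch lengths")
    rng = np.random.default_rng(seed)
    n_tips = genealogy.n_tips
    rates = subst.category_rates
    cat = rng.integers(len(rates), size=length)
    states = np.empty((genealogy.n_nodes, length), dtype=np.int64)
    root = genealogy.root
    states[root] = rng.choice(4, size=length, p=subst.base_frequencies)
    children = genealogy.children()
    order = [root]
    stack = list(children[root])
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(children[v])
    for v in order[1:]:
        cum = subst.transition_matrices(bl[v] * rates).cumsum(axis=-1)  # (ncat,4,4)
        u = rng.random(length)
        par = states[genealogy.parent[v]]
        states[v] = (cum[cat, par] < u[:, None]).sum(axis=1)
    base = np.array(list("ACGT"))
    seqs = ["".join(base[states[i]]) for i in range(n_tips)]
    return Alignment(seqs, list(genealogy.labels))


def simulate_split(
    history: SplitHistory, subst: SubstitutionModel, length: int, seed: int
) -> tuple[Alignment, Genealogy]:
    """Structured-coalescent simulation of a clean two-deme split.

    Each deme coalesces independently under its own demography until the
    split time; surviving lineages then merge into a single ancestral deme
    of constant size.  Returns the alignment plus the true labelled
    genealogy (populations 'A' and 'B' on the alignment)."""
    ss = np.random.SeedSequence(seed)
    rng_tree, seed_seq = ss.spawn(2)
    rng = np.random.default_rng(rng_tree)
    na, nb = history.sample_sizes
    n = na + nb
    n_nodes = 2 * n - 1
    times = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    next_node = n
    lin_a, _, next_node = _coalesce(
        list(range(na)), times, parent, _as_model(history.deme_sizes[0]),
        0.0, history.split_time, next_node, rng,
    )
    lin_b, _, next_node = _coalesce(
        list(range(na, n)), times, parent, _as_model(history.deme_sizes[1]),
        0.0, history.split_time, next_node, rng,
    )
    anc = TwoEpochModel(
        "exponential", history.ancestral_size, history.ancestral_size, 1.0
    )
    _coalesce(
        lin_a + lin_b, times, parent, anc, history.split_time, None, next_node, rng
    )
    labels = [f"A_{i:03d}" for i in range(na)] + [f"B_{i:03d}" for i in range(nb)]
    gen = Genealogy(parent, times, labels, time_units=MUTATION_UNITS)
    aln = simulate_sequences(gen, subst, length, seed=int(np.random.default_rng(seed_seq).integers(2**31)))
    aln.populations = ["A"] * na + ["B"] * nb
    return aln, gen


# ---------------------------------------------------------------------------
# temperature record
# ---------------------------------------------------------------------------

def synth_temperature(
    warming_onset: float = 12_000.0,
    warming_width: float = 2_000.0,
    amplitude: float = 8.0,
    noise_sd: float = 0.0,
    span: float = 25_000.0,
    step: float = 100.0,
    seed: int = 0,
) -> TemperatureRecord:
    """Sigmoidal deglacial warming centred at ``warming_onset`` years BP.

    The anomaly rises from about -amplitude (glacial) to about 0 (present)
    over a transition of scale ``warming_width`` (the 12%-88% width), with
    optional additive Gaussian noise.  The maximum warming rate occurs at
    the onset age by construction.
    """
    if not 0 < warming_onset < span:
        raise ValueError("warming_onset must lie inside (0, span)")
    if warming_width <= 0:
        raise ValueError("warming_width must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    ages = np.arange(0.0, span + step / 2, step)
    w = warming_width / 4.0
    temps = amplitude * (1.0 / (1.0 + np.exp((ages - warming_onset) / w)) - 1.0)
    if noise_sd > 0:
        temps = temps + np.random.default_rng(seed).normal(0.0, noise_sd, size=ages.size)
    return TemperatureRecord(ages, temps)


# ---------------------------------------------------------------------------
# fixture sets
# ---------------------------------------------------------------------------

DEFAULT_FIXTURES: dict = {
    "expansion_40x608": {
        "kind": "tem",
        "n": 40,
        "length": 608,
        "model": {
            "kind": "logistic",
            "theta_modern": 0.02,
            "theta_ancient": 0.0002,
            "transition_time": 2.5e-4,
        },
    },
    "constant_20x608": {
        "kind": "tem",
        "n": 20,
        "length": 608,
        "model": {
            "kind": "exponential",
            "theta_modern": 0.005,
            "theta_ancient": 0.005,
            "transition_time": 1e-3,
        },
    },
    "split_20x20x608": {
        "kind": "split",
        "length": 608,
        "split_time": 2.2e-3,
        "deme_theta": 0.004,
        "sample_sizes": [20, 20],
    },
    "temperature_12kya": {"kind": "temperature", "warming_onset": 12_000.0, "noise_sd": 0.3},
}


def _wrap_fasta(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def make_fixture_set(
    config: dict | None = None, outdir: str | Path = ".", root_seed: int = 20190101
) -> dict:
    """Write a deterministic fixture set (FASTA + Newick + parameter table +
    temperature CSV) and a manifest enumerating every fixture with its seed.

    Per-fixture seeds are the root seed's ``SeedSequence`` children in the
    sorted order of fixture names, so adding a fixture never perturbs the
    others' streams.
    """
    config = dict(DEFAULT_FIXTURES if config is None else config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = sorted(config)
    children = np.random.SeedSequence(root_seed).spawn(len(names))
    manifest: dict = {"root_seed": root_seed, "fixtures": {}}
    subst = SubstitutionModel(kappa=4.0, gamma_shape=0.5)
    for name, child in zip(names, children):
        spec = config[name]
        seed = int(np.random.default_rng(child).integers(2**31))
        entry: dict = {"seed": seed, "kind": spec["kind"]}
        if spec["kind"] == "tem":
            model = TwoEpochModel(**spec["model"])
            gen = simulate_coalescent(spec["n"], model, seed=seed)
            aln = simulate_sequences(gen, subst, spec["length"], seed=seed + 1)
            _write_fixture_alignment(outdir / f"{name}.fasta", aln)
            (outdir / f"{name}.nwk").write_text(gen.newick() + "\n")
            entry["true_params"] = spec["model"]
            entry["files"] = [f"{name}.fasta", f"{name}.nwk"]
        elif spec["kind"] == "split":
            hist = SplitHistory(
                split_time=spec["split_time"],
                deme_sizes=(spec["deme_theta"], spec["deme_theta"]),
                sample_sizes=tuple(spec["sample_sizes"]),
            )
            aln, gen = simulate_split(hist, subst, spec["length"], seed=seed)
            _write_fixture_alignment(outdir / f"{name}.fasta", aln)
            (outdir / f"{name}.nwk").write_text(gen.newick() + "\n")
            entry["true_params"] = {
                "split_time": spec["split_time"],
                "deme_theta": spec["deme_theta"],
            }
            entry["files"] = [f"{name}.fasta", f"{name}.nwk"]
        elif spec["kind"] == "temperature":
            rec = synth_temperature(
                warming_onset=spec.get("warming_onset", 12_000.0),
                noise_sd=spec.get("noise_sd", 0.0),
                seed=seed,
            )
            rec.to_csv(outdir / f"{name}.csv")
            entry["files"] = [f"{name}.csv"]
        else:
            raise ValueError(f"unknown fixture kind {spec['kind']!r}")
        manifest["fixtures"][name] = entry
    params_rows = [
        f"{name}\t{json.dumps(manifest['fixtures'][name].get('true_params', {}), sort_keys=True)}"
        for name in names
    ]
    (outdir / "true_params.tsv").write_text(
        "fixture\tparams_json\n" + "\n".join(params_rows) + "\n"
    )
    text = json.dumps(manifest, indent=2, sort_keys=True)
    manifest["manifest_sha256"] = hashlib.sha256(text.encode()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _write_fixture_alignment(path: Path, aln: Alignment) -> None:
    with open(path, "w") as fh:
        for lab, seq in zip(aln.labels, aln.sequences):
            fh.write(f">{lab}\n{_wrap_fasta(seq)}\n")
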