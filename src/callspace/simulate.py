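"""Synthetic study generator: trees, note characters, phonotaxis trials.

Everything downstream of data collection can be exercised with no field
data: Yule (pure-birth) trees stand in for the Bayesian tree sample, a
Gillespie simulation of the equal-rates Mk process evolves the note-number
character along them, and Bernoulli phonotaxis trials are drawn from a
unimodal (quadratic-on-logit) frequency response centered on each
population's call frequency, with note-dependent amplitude offsets.

The default eight populations mirror the real study design: their own note
counts, response-surface center frequencies and per-population trial counts
(72, 67, 89, 73, 72, 72, 80, 68 — 593 trials in total) follow the published
playback experiment, with stimuli at two, three and four notes.

Reproducibility: one integer seed drives everything.  It is expanded into
independent per-component streams through ``numpy.random.SeedSequence``
with fixed spawn keys (tree=0, character=1, population trials=10+index), so
each component can also be regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tree import PhyloTree, write_newick

__all__ = [
    "PopulationConfig",
    "SimTruth",
    "SyntheticStudy",
    "STUDY_POPULATIONS",
    "TESTED_VARIANTS",
    "PRESETS",
    "study_populations",
    "simulate_yule_tree",
    "simulate_mk_character",
    "simulate_trials",
    "make_preset",
    "write_study",
]

TESTED_VARIANTS = (2, 3, 4)   # note counts used as playback stimuli
S_STATES = 4
DEFAULT_SCALE_KHZ = 0.15      # width of the logit-quadratic frequency response
DEFAULT_HALFWIDTH_KHZ = 0.3   # stimulus frequencies span center +/- halfwidth
DEFAULT_AMPLITUDE = 2.0       # peak logit response to the favored variant
GRADED_STEP = -1.2            # logit penalty per note of distance (graded presets)
MATCHED_OFFSET = -12.0        # non-own offset under the matched construction:
                              # foreign variants are essentially never
                              # recognized (p < 5e-5), the defining feature
                              # of the matched-spaces scenario

# (name, own note count, call/center frequency kHz, trials) for the eight
# study populations of the playback experiment.
STUDY_POPULATIONS: tuple[tuple[str, int, float, int], ...] = (
    ("Careiro", 4, 3.12, 72),
    ("Leticia", 4, 3.08, 67),
    ("Hileia", 4, 3.10, 89),
    ("Ducke", 4, 2.87, 73),
    ("Panguana", 3, 3.07, 72),
    ("Catuaba", 2, 3.34, 72),
    ("Treviso", 4, 3.33, 80),
    ("Aratai", 4, 3.44, 68),
)

PRESETS = ("coupled", "null", "intermediate", "decoupled")


@dataclass
class PopulationConfig:
    """Generating parameters for one population's phonotaxis trials."""

    name: str
    own_note: int
    center_freq: float                  # kHz; stimulus frequencies center here
    note_offsets: dict[int, float]      # logit offset per tested note variant
    n_trials: int
    halfwidth: float = DEFAULT_HALFWIDTH_KHZ
    amplitude: float = DEFAULT_AMPLITUDE
    scale: float = DEFAULT_SCALE_KHZ
    surface_center: float | None = None  # defaults to center_freq

    def __post_init__(self) -> None:
        if self.n_trials < 20:
            raise ValueError("n_trials must be >= 20")
        if self.center_freq <= 0:
            raise ValueError("center_freq must be positive")
        if self.surface_center is None:
            self.surface_center = self.center_freq


@dataclass
class SimTruth:
    """Ground truth recorded alongside the observables."""

    node_states: dict[int, int] = field(default_factory=dict)
    edge_changes: list[dict] = field(default_factory=list)
    surfaces: dict[str, dict] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    preset: str
    seed: int
    tree: PhyloTree
    tip_states: dict[str, int]
    trials: pd.DataFrame
    populations: list[PopulationConfig]
    truth: SimTruth


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def simulate_yule_tree(
    n_tips: int, birth_rate: float, seed: int | np.random.Generator = 0,
    labels: list[str] | None = None,
) -> PhyloTree:
    """Pure-birth tree conditioned on ``n_tips`` extant lineages.

    Forward simulation from the root split: with ``k`` lineages the waiting
    time to the next birth is Exp(k * birth_rate); after the last split the
    pending lineages run for one further Exp(n * birth_rate) interval, so
    the tree is ultrametric with strictly positive pendant branches.  The
    expected height is (1/birth_rate) * sum_{k=2..n} 1/k.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, 0)
    if labels is not None and len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")

    parent = [-1, 0, 0]
    children = [[1, 2], [], []]
    birth_time = [0.0, None, None]   # None marks an open (extant) lineage
    t = 0.0
    open_lineages = [1, 2]
    while len(open_lineages) < n_tips:
        k = len(open_lineages)
        t += rng.exponential(1.0 / (k * birth_rate))
        v = open_lineages.pop(rng.integers(k))
        birth_time[v] = t
        for _ in range(2):
            parent.append(v)
            children[v].append(len(children))
            children.append([])
            birth_time.append(None)
            open_lineages.append(len(parent) - 1)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    height = t

    n_nodes = len(parent)
    start = np.zeros(n_nodes)
    for v in range(1, n_nodes):
        p = parent[v]
        start[v] = 0.0 if p == 0 else birth_time[p]
    end = np.array([height if bt is None else bt for bt in birth_time])
    lengths = end - start
    lengths[0] = 0.0

    lab: list[str | None] = [None] * n_nodes
    tip_idx = [v for v in range(n_nodes) if not children[v]]
    for j, v in enumerate(tip_idx):
        lab[v] = labels[j] if labels is not None else f"t{j + 1}"
    return PhyloTree(parent=np.array(parent), children=children,
                     edge_length=lengths, label=lab, root=0)


def simulate_mk_character(
    tree: PhyloTree, q: float, S: int = S_STATES, root_state: int = 4,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, int], SimTruth]:
    """Evolve a discrete character along the tree under ER(q) by Gillespie.

    On an edge of length ``t`` the waiting time to the next change is
    Exp((S-1) * q) and the new state is uniform among the other S-1 states;
    every change event is recorded with its edge and direction.
    """
    if q < 0:
        raise ValueError("rate must be nonnegative")
    if not 1 <= root_state <= S:
        raise ValueError("root_state outside 1..S")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, 1)
    truth = SimTruth()
    states = {tree.root: root_state}
    total_rate = (S - 1) * q
    for v in tree.preorder():
        if v == tree.root:
            continue
        s = states[tree.parent[v]]
        remaining = tree.edge_length[v]
        if total_rate > 0:
            while True:
                wait = rng.exponential(1.0 / total_rate)
                if wait >= remaining:
                    break
                remaining -= wait
                new = int(rng.integers(1, S))  # uniform over the other S-1
                if new >= s:
                    new += 1
                truth.edge_changes.append(
                    {"child_node": int(v), "from": s, "to": new})
                s = new
        states[v] = s
    truth.node_states = {int(k): int(v) for k, v in states.items()}
    tip_states = {tree.label[v]: states[v] for v in tree.tips}
    return tip_states, truth


def simulate_trials(
    pop: PopulationConfig, seed: int | np.random.Generator = 0,
    variants: tuple[int, ...] = TESTED_VARIANTS,
) -> tuple[pd.DataFrame, dict]:
    """Draw one population's Bernoulli phonotaxis trials.

    Stimulus frequencies are uniform on center +/- halfwidth; note variants
    are uniform over ``variants``;
    logit p = amplitude + note_offset(k) - ((f - surface_center) / scale)^2.
    Returns the trial rows and the generating-surface record.
    """
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, 10)
    f = rng.uniform(pop.center_freq - pop.halfwidth,
                    pop.center_freq + pop.halfwidth, pop.n_trials)
    notes = np.array(variants)[rng.integers(0, len(variants), pop.n_trials)]
    offsets = np.array([pop.note_offsets[k] for k in notes])
    eta = pop.amplitude + offsets - ((f - pop.surface_center) / pop.scale) ** 2
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.uniform(size=pop.n_trials) < p).astype(int)
    df = pd.DataFrame({
        "population": pop.name,
        "stimulus_notes": notes.astype(int),
        "stimulus_freq_khz": f,
        "response": y,
    })
    surface = {
        "own_note": pop.own_note, "center_freq": pop.center_freq,
        "surface_center": pop.surface_center, "scale": pop.scale,
        "amplitude": pop.amplitude,
        "note_offsets": {int(k): float(v) for k, v in pop.note_offsets.items()},
        "n_trials": pop.n_trials,
    }
    return df, surface


def _graded_offsets(favored: int, variants=TESTED_VARIANTS) -> dict[int, float]:
    return {k: GRADED_STEP * abs(k - favored) for k in variants}


def _matched_offsets(own: int, variants=TESTED_VARIANTS) -> dict[int, float]:
    return {k: 0.0 if k == own else MATCHED_OFFSET for k in variants}


def study_populations(
    preset: str, own_notes: dict[str, int] | None = None
) -> list[PopulationConfig]:
    """Population configs for a preset, on the study's eight-population design.

    * ``null``         — all note offsets equal: recognition ignores notes.
    * ``intermediate`` — graded offsets favoring the own note.
    * ``coupled``      — matched surfaces: only the own note is recognized.
    * ``decoupled``    — every surface favors four notes (the prevalent,
      putatively ancestral state) regardless of the population's own call,
      so the three- and two-note senders' receivers track the ancestor.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    pops = []
    for name, own, freq, n in STUDY_POPULATIONS:
        own = own_notes.get(name, own) if own_notes else own
        if preset == "null":
            offsets = {k: 0.0 for k in TESTED_VARIANTS}
            amplitude = 1.5
        elif preset == "intermediate":
            offsets = _graded_offsets(own)
            amplitude = DEFAULT_AMPLITUDE
        elif preset == "coupled":
            offsets = _matched_offsets(own)
            amplitude = DEFAULT_AMPLITUDE
        else:  # decoupled: surfaces stuck on the ancestral four-note call
            offsets = _graded_offsets(4)
            amplitude = DEFAULT_AMPLITUDE
        pops.append(PopulationConfig(
            name=name, own_note=own, center_freq=freq,
            note_offsets=offsets, n_trials=n, amplitude=amplitude))
    return pops


def make_preset(
    preset: str, seed: int = 0, birth_rate: float = 1.0, mk_rate: float = 0.3
) -> SyntheticStudy:
    """Full synthetic study: tree + note states + trials for 8 populations.

    For the ``coupled`` preset the tip states come from the Mk simulation
    and each population's own call is set to its simulated state (sender
    and receiver move together).  The other presets keep the study's
    observed note numbers as tip states and vary only the response
    surfaces.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    names = [p[0] for p in STUDY_POPULATIONS]
    tree = simulate_yule_tree(len(names), birth_rate, _rng(seed, 0), labels=names)
    if preset == "coupled":
        tip_states, truth = simulate_mk_character(
            tree, mk_rate, S_STATES, root_state=4, seed=_rng(seed, 1))
        own_notes = dict(tip_states)
        # one-note calls were never used as playback stimuli; fold state 1
        # into the nearest tested variant so every sender can be tested
        own_notes = {k: max(v, TESTED_VARIANTS[0]) for k, v in own_notes.items()}
        tip_states = dict(own_notes)
        pops = study_populations(preset, own_notes)
    else:
        tip_states = {name: own for name, own, _, _ in STUDY_POPULATIONS}
        truth = SimTruth(node_states={}, edge_changes=[])
        pops = study_populations(preset)
    frames = []
    for i, pop in enumerate(pops):
        df, surface = simulate_trials(pop, _rng(seed, 10 + i))
        frames.append(df)
        truth.surfaces[pop.name] = surface
    trials = pd.concat(frames, ignore_index=True)
    return SyntheticStudy(preset=preset, seed=seed, tree=tree,
                          tip_states=tip_states, trials=trials,
                          populations=pops, truth=truth)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Emit the study as the plain-text formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "traits": outdir / "traits.csv",
        "trials": outdir / "trials.csv",
        "truth": outdir / "truth.json",
    }
    paths["tree"].write_text(write_newick(study.tree) + "\n")
    traits = pd.DataFrame(
        sorted(study.tip_states.items()), columns=["tip_label", "state"])
    traits.to_csv(paths["traits"], index=False)
    trials = study.trials.copy()
    trials["stimulus_freq_khz"] = trials["stimulus_freq_khz"].map(
        lambda v: format(v, ".10g"))
    trials.to_csv(paths["trials"], index=False)
    truth = {
        "preset": study.preset, "seed": study.seed,
        "node_states": study.truth.node_states,
        "edge_changes": study.truth.edge_changes,
        "surfaces": study.truth.surfaces,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths
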