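"""Simulated experimental sessions: trial protocol and Poisson spiking.

The default protocol mirrors the characterization experiment: 7 stimulus
types x 1024 examples x 2 repeats, each presented for 320 ms with no
inter-trial gap, interleaved in a seeded pseudorandom order.  Spikes are
drawn from an inhomogeneous Poisson process at 1 ms resolution from the
model-neuron rate.  Sessions round-trip through CSV (one row per trial,
spike times semicolon-separated, in seconds from trial onset) with a JSON
sidecar holding the protocol and, for simulated data, the ground-truth
neuron parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .neurons import NeuronModelSpec, TransientKernel, board_drive
from .textures import KINDS

__all__ = [
    "ProtocolSpec",
    "TrialRecord",
    "Session",
    "build_protocol",
    "presentation_order",
    "simulate_session",
]


@dataclass(frozen=True)
class ProtocolSpec:
    n_examples_per_set: int = 1024
    n_repeats: int = 2
    presentation_ms: float = 320.0
    set_kinds: tuple[str, ...] = KINDS
    check_size_deg: float = 0.2  # metadata only
    inter_trial_ms: float = 0.0
    interleave_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_examples_per_set < 1 or self.n_repeats < 1:
            raise ValueError("counts must be positive")
        if self.presentation_ms <= 0:
            raise ValueError("presentation_ms must be positive")
        if self.inter_trial_ms < 0:
            raise ValueError("inter_trial_ms must be nonnegative")

    @property
    def n_trials(self) -> int:
        return len(self.set_kinds) * self.n_examples_per_set * self.n_repeats


def build_protocol(**overrides) -> ProtocolSpec:
    """Fully-specified protocol; see :class:`ProtocolSpec` for defaults."""
    return ProtocolSpec(**overrides)


def presentation_order(protocol: ProtocolSpec) -> list[tuple[str, int, int]]:
    """Seeded uniform random permutation of all (kind, example, repeat) triples."""
    triples = [
        (kind, ex, rep)
        for kind in protocol.set_kinds
        for ex in range(protocol.n_examples_per_set)
        for rep in range(protocol.n_repeats)
    ]
    rng = np.random.default_rng(protocol.interleave_seed)
    perm = rng.permutation(len(triples))
    return [triples[i] for i in perm]


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    stim_kind: str
    example_id: int
    onset_s: float
    spike_times_s: np.ndarray  # offsets from onset, within [0, presentation)


@dataclass
class Session:
    """An ordered list of trials plus the protocol that produced them."""

    protocol: ProtocolSpec
    trials: list[TrialRecord]
    neuron_truth: NeuronModelSpec | None = None

    def __post_init__(self) -> None:
        onsets = [t.onset_s for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")

    @property
    def kinds(self) -> tuple[str, ...]:
        return self.protocol.set_kinds

    def trials_of_kind(self, kind: str) -> list[TrialRecord]:
        out = [t for t in self.trials if t.stim_kind == kind]
        if not out:
            raise KeyError(f"session contains no trials of kind {kind!r}")
        return out

    def n_spikes(self) -> int:
        return int(sum(len(t.spike_times_s) for t in self.trials))

    def duration_s(self) -> float:
        last = self.trials[-1]
        return last.onset_s + self.protocol.presentation_ms / 1000.0

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": [t.trial_index for t in self.trials],
                "stim_kind": [t.stim_kind for t in self.trials],
                "example_id": [t.example_id for t in self.trials],
                "onset_s": [t.onset_s for t in self.trials],
                "spike_times_s": [
                    ";".join(f"{s:.6f}" for s in t.spike_times_s) for t in self.trials
                ],
            }
        )

    def save(self, csv_path: str | Path) -> None:
        """Write trials as CSV plus a JSON sidecar (.json) with metadata."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        meta: dict = {"protocol": dataclasses.asdict(self.protocol)}
        if self.neuron_truth is not None:
            meta["neuron_truth"] = dataclasses.asdict(self.neuron_truth)
        csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, csv_path: str | Path) -> "Session":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path, keep_default_na=False)
        meta_path = csv_path.with_suffix(".json")
        neuron = None
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            p = meta["protocol"]
            p["set_kinds"] = tuple(p["set_kinds"])
            protocol = ProtocolSpec(**p)
            if "neuron_truth" in meta:
                nt = meta["neuron_truth"]
                nt["kernel"] = TransientKernel(**nt["kernel"])
                nt["pooling"] = tuple(
                    (tuple(off), s) for off, s in nt["pooling"]
                )
                nt["patch_origin"] = tuple(nt["patch_origin"])
                nt["patch_weights"] = tuple(
                    tuple(row) for row in nt["patch_weights"]
                )
                neuron = NeuronModelSpec(**nt)
        else:
            kinds = tuple(dict.fromkeys(df["stim_kind"]))
            protocol = ProtocolSpec(
                n_examples_per_set=int(df["example_id"].max()) + 1,
                n_repeats=max(
                    1, len(df) // ((int(df["example_id"].max()) + 1) * len(kinds))
                ),
                set_kinds=kinds,
            )
        trials = [
            TrialRecord(
                trial_index=int(r.trial_index),
                stim_kind=str(r.stim_kind),
                example_id=int(r.example_id),
                onset_s=float(r.onset_s),
                spike_times_s=np.array(
                    [float(s) for s in str(r.spike_times_s).split(";") if s],
                    dtype=float,
                ),
            )
            for r in df.itertuples()
        ]
        return cls(protocol=protocol, trials=trials, neuron_truth=neuron)


def _poisson_spikes(
    rate_hz: np.ndarray, dt_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous Poisson sampling: independent counts per dt bin, spike
    times uniform within their bin."""
    counts = rng.poisson(rate_hz * dt_s)
    n = int(counts.sum())
    if n == 0:
        return np.empty(0)
    bins = np.repeat(np.arange(rate_hz.size), counts)
    times = (bins + rng.random(n)) * dt_s
    return np.sort(times)


def simulate_session(
    neuron: NeuronModelSpec,
    ensembles: dict[str, np.ndarray] | None,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    dt_ms: float = 1.0,
) -> Session:
    """Simulate a full experimental session for one model neuron.

    ``ensembles`` maps each protocol kind to its board stack; it may be None
    only for a null (stimulus-independent) neuron.  Spiking is Poisson at
    ``dt_ms`` resolution; consecutive presentations abut in session time
    unless the protocol specifies an inter-trial gap.
    """
    if protocol is None:
        protocol = build_protocol()
    if ensembles is None:
        if neuron.model_class != "null":
            raise ValueError("ensembles are required for stimulus-driven neurons")
        ensembles = {}
    else:
        for kind in protocol.set_kinds:
            if kind not in ensembles:
                raise ValueError(f"missing ensemble for kind {kind!r}")
            if ensembles[kind].shape[0] < protocol.n_examples_per_set:
                raise ValueError(
                    f"ensemble {kind!r} has fewer boards than the protocol needs"
                )

    rng = np.random.default_rng(seed)
    t_ms = np.arange(0.0, protocol.presentation_ms, dt_ms)
    kern = neuron.kernel(t_ms)
    dt_s = dt_ms / 1000.0
    # Precompute per-(kind, example) drives in one vectorized pass per kind.
    gains: dict[str, np.ndarray] = {}
    for kind in protocol.set_kinds:
        if neuron.model_class == "null":
            gains[kind] = np.zeros(protocol.n_examples_per_set)
        else:
            drives = board_drive(
                neuron, ensembles[kind][: protocol.n_examples_per_set]
            )
            gains[kind] = np.asarray(drives) / neuron.drive_scale

    step_s = (protocol.presentation_ms + protocol.inter_trial_ms) / 1000.0
    trials = []
    for i, (kind, ex, _rep) in enumerate(presentation_order(protocol)):
        rate = neuron.baseline_rate_hz + neuron.peak_rate_hz * gains[kind][ex] * kern
        np.maximum(rate, 0.0, out=rate)
        spikes = _poisson_spikes(rate, dt_s, rng)
        trials.append(
            TrialRecord(
                trial_index=i,
                stim_kind=kind,
                example_id=ex,
                onset_s=i * step_s,
                spike_times_s=spikes,
            )
        )
    return Session(protocol=protocol, trials=trials, neuron_truth=neuron)
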