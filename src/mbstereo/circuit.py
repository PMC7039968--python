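"""Random PN -> KC -> MBON feedforward network for a pair of individuals.

The model has three layers: ``n_pns`` projection neurons (PNs) whose odor
responses are stereotyped across individuals, ``n_kcs`` Kenyon cells (KCs)
receiving input through a random binary PN-KC connection matrix drawn
independently per individual, and a mushroom-body output neuron (MBON)
reading a fixed KC subset shared by all individuals through the same
rectifier applied to its summed input.

For a given odor each PN responds with probability ``pn_response_prob`` and
emits a uniform integer spike count in [spike_low, spike_high]; silent PNs
emit 0.  KC responses use the rectifier f(k) = max(0, k - t) on the summed
PN input k; the default threshold t = 119 makes ~10% of KCs respond per
odor.  At the defaults (50 PNs, connection probability 0.14) each KC is
connected to 7 PNs on average, and the MBON reads the first 1000 of the
2000 KCs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from .metrics import ResponseTable

__all__ = [
    "NetworkParams",
    "PNResponseSet",
    "IndividualPair",
    "PopulationReadout",
    "sample_pn_responses",
    "sample_individual_pair",
    "forward_pass",
    "linear_forward",
    "calibrate_linear_gain",
    "batch_forward",
    "summarize_population",
    "mbon_weights",
]


@dataclass(frozen=True)
class NetworkParams:
    """Every simulator knob; the defaults are the reference conditions."""

    n_pns: int = 50
    n_kcs: int = 2000
    pn_kc_prob: float = 0.14
    kc_threshold: float = 119.0
    kc_mbon_prob: float = 0.5
    pn_response_prob: float = 0.5
    spike_low: int = 10
    spike_high: int = 30
    n_odors: int = 100
    n_individuals: int = 2
    randomness_fraction: float = 1.0
    noise_sd: float = 0.0
    mbon_threshold: float | None = None  # None -> same rectifier t as KCs
    seed: int = 0

    def __post_init__(self):
        for name in ("pn_kc_prob", "kc_mbon_prob", "pn_response_prob",
                     "randomness_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.spike_low > self.spike_high:
            raise ValueError("spike_low must be <= spike_high")
        if self.kc_threshold < 0:
            raise ValueError("kc_threshold must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("n_pns", "n_kcs", "n_odors", "n_individuals"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def with_(self, **kwargs) -> "NetworkParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def mean_spike_rate(self) -> float:
        return 0.5 * (self.spike_low + self.spike_high)

    @property
    def mbon_t(self) -> float:
        """MBON rectifier threshold; defaults to the KC threshold (both
        layers use the same rectifier)."""
        return (self.kc_threshold if self.mbon_threshold is None
                else self.mbon_threshold)


@dataclass
class PNResponseSet:
    """Odors x PNs integer spike counts, shared across individuals unless
    the non-stereotypic-PN control draws one set per individual."""

    spikes: np.ndarray
    shared_across_individuals: bool = True

    @property
    def total_per_odor(self) -> np.ndarray:
        return self.spikes.sum(axis=1)


@dataclass
class IndividualPair:
    """Per-individual boolean PN-KC matrices plus the shared KC-MBON mask."""

    pn_kc: list  # list of (n_pns, n_kcs) bool arrays, one per individual
    kc_mbon_mask: np.ndarray  # (n_kcs,) bool, identical across individuals


@dataclass
class PopulationReadout:
    """Per-odor, per-individual derived quantities of one forward pass."""

    kc_input: np.ndarray
    kc_response: np.ndarray
    mbon_response: float
    total_kc_input: float
    total_kc_response: float
    n_active_kcs: int
    mean_active_rate: float


def sample_pn_responses(params: NetworkParams, rng: np.random.Generator,
                        n_odors: int | None = None) -> PNResponseSet:
    """Draw the PN spike-count matrix for a panel of odors.

    Each PN responds to each odor independently with ``pn_response_prob``;
    responders draw a uniform integer in [spike_low, spike_high] inclusive
    (mean 20 at the defaults), non-responders emit exactly 0 spikes.
    """
    n_odors = params.n_odors if n_odors is None else n_odors
    shape = (n_odors, params.n_pns)
    responding = rng.random(shape) < params.pn_response_prob
    counts = rng.integers(params.spike_low, params.spike_high + 1, size=shape)
    return PNResponseSet(spikes=np.where(responding, counts, 0))


def sample_individual_pair(params: NetworkParams, rng: np.random.Generator,
                           mask_mode: str = "first") -> IndividualPair:
    """Draw per-individual PN-KC matrices and the shared KC-MBON mask.

    Individual 1's matrix is i.i.d. Bernoulli(pn_kc_prob) per entry; each
    further individual copies it and independently redraws each entry with
    probability ``randomness_fraction`` (0 = identical wiring, 1 = fully
    independent).  ``mask_mode`` selects the KC-MBON subset: ``"first"``
    takes the first ceil(kc_mbon_prob * n_kcs) KCs (the default network),
    ``"bernoulli"`` draws a Bernoulli(kc_mbon_prob) mask shared by both
    individuals (used in convergence sweeps).
    """
    shape = (params.n_pns, params.n_kcs)
    base = rng.random(shape) < params.pn_kc_prob
    matrices = [base]
    for _ in range(params.n_individuals - 1):
        redraw = rng.random(shape) < params.randomness_fraction
        fresh = rng.random(shape) < params.pn_kc_prob
        matrices.append(np.where(redraw, fresh, base))
    if mask_mode == "first":
        n_on = int(np.ceil(params.kc_mbon_prob * params.n_kcs))
        mask = np.zeros(params.n_kcs, dtype=bool)
        mask[:n_on] = True
    elif mask_mode == "bernoulli":
        mask = rng.random(params.n_kcs) < params.kc_mbon_prob
    else:
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    return IndividualPair(pn_kc=matrices, kc_mbon_mask=mask)


def mbon_weights(mask: np.ndarray, normalize: bool = False) -> np.ndarray:
    """KC -> MBON weight vector: 1 on the mask, 0 off.

    With ``normalize`` the mean weight over all KCs is subtracted, the
    mean-zero weight normalization that abolishes readout stereotypy.
    """
    w = mask.astype(float)
    if normalize:
        w = w - w.mean()
    return w


def _kc_inputs(pn_vector: np.ndarray, conn: np.ndarray, noise_sd: float,
               rng: np.random.Generator | None) -> np.ndarray:
    k = pn_vector.astype(float) @ conn
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        k = np.maximum(0.0, k + rng.normal(0.0, noise_sd, size=k.shape))
    return k


def _readout(kc_input: np.ndarray, kc_response: np.ndarray,
             weights: np.ndarray, mbon_t: float) -> PopulationReadout:
    active = kc_response > 0
    n_active = int(np.count_nonzero(active))
    total_resp = float(kc_response.sum())
    return PopulationReadout(
        kc_input=kc_input,
        kc_response=kc_response,
        mbon_response=max(0.0, float(kc_response @ weights) - mbon_t),
        total_kc_input=float(kc_input.sum()),
        total_kc_response=total_resp,
        n_active_kcs=n_active,
        mean_active_rate=float(kc_response[active].mean()) if n_active else 0.0,
    )


def forward_pass(pn_vector: np.ndarray, conn: np.ndarray, mask: np.ndarray,
                 t: float, noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None,
                 normalize_mbon_weights: bool = False,
                 mbon_threshold: float | None = None) -> PopulationReadout:
    """One odor through one individual's network with the rectifier.

    k_i is the summed spike count of the PNs connected to KC i (plus
    optional truncated Gaussian input noise); the response is
    max(0, k_i - t).  The MBON applies the same rectifier to the sum of
    the masked KC responses, with its threshold defaulting to ``t``
    (pass ``mbon_threshold=0`` for a plain sum).
    """
    if t < 0:
        raise ValueError("threshold must be non-negative")
    k = _kc_inputs(np.asarray(pn_vector), conn, noise_sd, rng)
    r = np.maximum(0.0, k - t)
    mbon_t = t if mbon_threshold is None else mbon_threshold
    return _readout(k, r, mbon_weights(mask, normalize_mbon_weights), mbon_t)


def linear_forward(pn_vector: np.ndarray, conn: np.ndarray, mask: np.ndarray,
                   t: float, m: float) -> PopulationReadout:
    """One odor through a linear KC transfer y_i = m*k_i - t (no rectifier).

    Negative responses are kept; all summaries are computed on the signed
    values.  ``m`` normally comes from :func:`calibrate_linear_gain`.
    """
    if m <= 0:
        raise ValueError("linear gain m must be positive")
    k = _kc_inputs(np.asarray(pn_vector), conn, 0.0, None)
    r = m * k - t
    return _readout(k, r, mbon_weights(mask), mbon_t=t)


def calibrate_linear_gain(kc_inputs: np.ndarray, t: float) -> float:
    """Gain m matching linear and rectified grand-mean total KC responses.

    ``kc_inputs`` stacks the KC input vectors of every (odor, individual)
    combination of one iteration.  Solves
    mean_over_cases[ sum_i (m*k_i - t) ] = mean_over_cases[ sum_i max(0, k_i - t) ]
    which is linear in m.
    """
    k = np.asarray(kc_inputs, dtype=float)
    if k.ndim == 1:
        k = k[None, :]
    mean_total_input = k.sum(axis=-1).mean()
    if mean_total_input <= 0:
        raise ValueError("cannot calibrate linear gain on all-zero inputs")
    target = np.maximum(0.0, k - t).sum(axis=-1).mean()
    n_kcs = k.shape[-1]
    return float((target + n_kcs * t) / mean_total_input)


def batch_forward(spikes: np.ndarray, conn: np.ndarray, t: float,
                  noise_sd: float = 0.0,
                  rng: np.random.Generator | None = None):
    """Vectorized rectified pass: (odors, PNs) spikes -> per-odor arrays.

    Returns ``(kc_inputs, kc_responses)`` with shape (odors, n_kcs) each.
    Equivalent to calling :func:`forward_pass` per odor; used by the
    experiment runners for speed.
    """
    k = spikes.astype(float) @ conn
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        k = np.maximum(0.0, k + rng.normal(0.0, noise_sd, size=k.shape))
    return k, np.maximum(0.0, k - t)


def summarize_population(readouts) -> dict:
    """Reshape a full individuals x odors grid of readouts into tables.

    ``readouts`` is a nested sequence ``readouts[individual][odor]`` of
    :class:`PopulationReadout`.  Returns one :class:`ResponseTable` per
    scalar quantity plus the stacked per-KC response arrays under
    ``"kc_responses"`` (individuals, odors, n_kcs).
    """
    n_ind = len(readouts)
    lengths = {len(row) for row in readouts}
    if len(lengths) != 1:
        raise ValueError("ragged readout grid: unequal odor counts")
    fields = ("mbon_response", "total_kc_response", "total_kc_input",
              "n_active_kcs", "mean_active_rate")
    out = {}
    for name in fields:
        vals = np.array([[getattr(r, name) for r in row] for row in readouts],
                        dtype=float)
        out[name] = ResponseTable(vals)
    out["kc_responses"] = np.stack(
        [np.stack([r.kc_response for r in row]) for row in readouts])
    return out
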