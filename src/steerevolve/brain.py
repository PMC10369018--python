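"""The steering brain: a 2-input, one-hidden-layer, 1-output sigmoid MLP.

The network is memoryless and reactive: it maps the normalized wall cues
``(d_w_norm, theta_w_norm)`` to a single output ``o1 in (0, 1)``, with the
logistic sigmoid applied at the hidden neurons and at the output neuron.
The turn per time step is ``dphi = (o1 - 0.5) * i_steering``.

For ``n_hidden`` hidden neurons the parameter count is ``4*n_hidden + 1``
(two input weights and one bias per hidden neuron, one output weight per
hidden neuron, one output bias); the reference 2-3-1 network has 13.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class BrainParams:
    """Weights and biases of the steering network.

    ``hidden_weights[k] = (w_k_dist, w_k_angle)`` feed hidden neuron ``k``.
    """

    hidden_weights: np.ndarray  # shape (n_hidden, 2)
    hidden_biases: np.ndarray  # shape (n_hidden,)
    output_weights: np.ndarray  # shape (n_hidden,)
    output_bias: float

    def __post_init__(self) -> None:
        hw = np.asarray(self.hidden_weights, dtype=float)
        hb = np.asarray(self.hidden_biases, dtype=float)
        ow = np.asarray(self.output_weights, dtype=float)
        if hw.ndim != 2 or hw.shape[1] != 2:
            raise ValueError("hidden_weights must have shape (n_hidden, 2)")
        n = hw.shape[0]
        if n < 1:
            raise ValueError("at least one hidden neuron is required")
        if hb.shape != (n,) or ow.shape != (n,):
            raise ValueError("hidden_biases and output_weights must have shape (n_hidden,)")
        object.__setattr__(self, "hidden_weights", hw)
        object.__setattr__(self, "hidden_biases", hb)
        object.__setattr__(self, "output_weights", ow)
        object.__setattr__(self, "output_bias", float(self.output_bias))

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    @classmethod
    def zeros(cls, n_hidden: int = 3) -> "BrainParams":
        """All-zero network; its output is 0.5 everywhere (straight motion)."""
        return cls(
            hidden_weights=np.zeros((n_hidden, 2)),
            hidden_biases=np.zeros(n_hidden),
            output_weights=np.zeros(n_hidden),
            output_bias=0.0,
        )


def param_count(n_hidden: int) -> int:
    """Total number of weights and biases: ``4*n_hidden + 1``."""
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    return 4 * n_hidden + 1


def forward(params: BrainParams, dist_norm, angle_norm):
    """Evaluate the network on normalized inputs (scalars or arrays).

    ``o1 = sigmoid(b_out + sum_k v_k * sigmoid(b_k + w_k1*d + w_k2*t))``.
    Broadcasting over array inputs returns an array of matching shape.
    """
    _check_finite(params)
    d = np.asarray(dist_norm, dtype=float)
    t = np.asarray(angle_norm, dtype=float)
    w = params.hidden_weights
    z = params.hidden_biases + w[:, 0] * d[..., None] + w[:, 1] * t[..., None]
    h = expit(z)
    o1 = expit(params.output_bias + np.sum(params.output_weights * h, axis=-1))
    if d.ndim == 0 and t.ndim == 0:
        return float(o1)
    return o1


def steering_angle(o1, i_steering: float):
    """Map the network output to a turning angle: ``(o1 - 0.5) * i_steering``."""
    result = (np.asarray(o1, dtype=float) - 0.5) * i_steering
    if np.ndim(o1) == 0:
        return float(result)
    return result


def pack(params: BrainParams) -> np.ndarray:
    """Flatten to a genome: hidden weights row-major, hidden biases,
    output weights, output bias."""
    return np.concatenate(
        [
            params.hidden_weights.ravel(),
            params.hidden_biases,
            params.output_weights,
            [params.output_bias],
        ]
    )


def unpack(genome: np.ndarray, n_hidden: int) -> BrainParams:
    """Inverse of :func:`pack`; the genome length must equal ``4*n_hidden + 1``."""
    genome = np.asarray(genome, dtype=float)
    expected = param_count(n_hidden)
    if genome.shape != (expected,):
        raise ValueError(
            f"genome of length {genome.size} does not match n_hidden={n_hidden} "
            f"(expected {expected})"
        )
    h = n_hidden
    return BrainParams(
        hidden_weights=genome[: 2 * h].reshape(h, 2).copy(),
        hidden_biases=genome[2 * h : 3 * h].copy(),
        output_weights=genome[3 * h : 4 * h].copy(),
        output_bias=float(genome[4 * h]),
    )


def _check_finite(params: BrainParams) -> None:
    if not (
        np.all(np.isfinite(params.hidden_weights))
        and np.all(np.isfinite(params.hidden_biases))
        and np.all(np.isfinite(params.output_weights))
        and np.isfinite(params.output_bias)
    ):
        raise ValueError("brain parameters must all be finite")
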