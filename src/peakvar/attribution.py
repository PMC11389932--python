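"""Contribution scores for sequence CNNs.

Implements rescale-rule multiplier propagation (the DeepLIFT rule underlying
DeepSHAP): the difference of the model output from its output on a chosen
reference input is decomposed over input positions. Linear layers propagate
multipliers like gradients; each nonlinearity uses the finite-difference
slope delta_out / delta_in between the actual and the reference activation
(falling back to the local derivative when delta_in vanishes); max-pool
windows route their pooled delta through the forward-pass argmax. The
resulting attributions satisfy completeness exactly up to float error:

    sum over positions and bases of attribution = f(x) - f(reference).

The default reference is the all-zero matrix — a sequence of unknown (N)
bases — so the scores describe what the model sees relative to "no sequence".
"""

from __future__ import annotations

import numpy as np

from . import nn

_EPS = 1e-9


def _forward_trace(network, x):
    """Evaluation-mode forward pass recording every layer's input."""
    acts = []
    out = np.asarray(x, dtype=np.float64)
    for layer in network.layers:
        acts.append(out)
        out = layer.forward(out, training=False)
    return acts, out


def _conv_multiplier(layer: nn.Conv1D, m_out, in_shape):
    N, L_out, F = m_out.shape
    dcols = (m_out @ layer.W.T).reshape(N, L_out, layer.kernel, layer.in_channels)
    m_in = np.zeros(in_shape)
    offsets = layer.stride * np.arange(L_out)
    for j in range(layer.kernel):
        m_in[:, offsets + j, :] += dcols[:, :, j, :]
    return m_in


def deeplift_multipliers(network: nn.Network, x, reference):
    """Input-space multipliers m with sum(m * (x - ref)) = f(x) - f(ref)."""
    acts_x, out_x = _forward_trace(network, x)
    acts_r, out_r = _forward_trace(network, reference)

    m = np.ones_like(out_x)  # d f / d f
    for layer, ax, ar in zip(reversed(network.layers),
                             reversed(acts_x), reversed(acts_r)):
        if isinstance(layer, nn.Dense):
            m = m @ layer.W.T
        elif isinstance(layer, nn.Conv1D):
            m = _conv_multiplier(layer, m, ax.shape)
        elif isinstance(layer, nn.Flatten):
            m = m.reshape(ax.shape)
        elif isinstance(layer, nn.Dropout):
            pass  # identity at evaluation
        elif isinstance(layer, nn.ReLU):
            din = ax - ar
            dout = np.maximum(ax, 0.0) - np.maximum(ar, 0.0)
            slope = np.where(np.abs(din) > _EPS, dout / np.where(din == 0, 1, din),
                             (ax > 0).astype(float))
            m = m * slope
        elif isinstance(layer, nn.Sigmoid):
            din = ax - ar
            dout = nn.sigmoid(ax) - nn.sigmoid(ar)
            sx = nn.sigmoid(ax)
            slope = np.where(np.abs(din) > _EPS, dout / np.where(din == 0, 1, din),
                             sx * (1.0 - sx))
            m = m * slope
        elif isinstance(layer, nn.MaxPool1D):
            # route each window's pooled delta through the argmax at x
            wins_x = np.lib.stride_tricks.sliding_window_view(
                ax, layer.size, axis=1)[:, :: layer.stride]
            wins_r = np.lib.stride_tricks.sliding_window_view(
                ar, layer.size, axis=1)[:, :: layer.stride]
            arg = wins_x.argmax(axis=-1)  # (N, L_out, C)
            dpool = wins_x.max(axis=-1) - wins_r.max(axis=-1)
            N, L_out, C = arg.shape
            n_idx, l_idx, c_idx = np.meshgrid(
                np.arange(N), np.arange(L_out), np.arange(C), indexing="ij")
            pos = arg + layer.stride * l_idx
            din = ax[n_idx, pos, c_idx] - ar[n_idx, pos, c_idx]
            slope = np.where(np.abs(din) > _EPS,
                             dpool / np.where(din == 0, 1, din), 1.0)
            m_in = np.zeros(ax.shape)
            np.add.at(m_in, (n_idx, pos, c_idx), m * slope)
            m = m_in
        else:  # pragma: no cover - every layer type is handled above
            raise TypeError(f"no multiplier rule for layer {type(layer).__name__}")
    return m, out_x, out_r


def contribution_scores(results, onehot, reference=None) -> np.ndarray:
    """L x 4 attribution matrix for one sequence (or a batch of them).

    ``reference`` defaults to the all-zero (all-N) input. For classifiers the
    decomposed quantity is the pre-sigmoid output, keeping the attribution on
    the unbounded logit scale.
    """
    x = np.asarray(onehot, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    L = results.spec.input_length
    if x.shape[1:] != (L, 4):
        raise ValueError(f"expected shape (n, {L}, 4), got {x.shape}")
    if reference is None:
        reference = np.zeros_like(x)
    else:
        reference = np.asarray(reference, dtype=np.float64)
        if reference.ndim == 2:
            reference = np.broadcast_to(reference[None], x.shape).copy()
    m, _, _ = deeplift_multipliers(results.network, x, reference)
    attrib = m * (x - reference)
    return attrib[0] if single else attrib
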