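"""Symbolic transfer entropy and directed brain-network construction.

Each channel is reduced to a sequence of ordinal symbols: every window of
``embed_m`` values at spacing ``delay_tau`` is mapped to the lexicographic
rank of the permutation that sorts it (ties broken earlier-index-first).
The symbolic transfer entropy from a driver J to a target I is the
plug-in estimate of

    STE(J->I) = sum p(s_I[n+1], s_I[n], s_J[n])
                    * log[ p(s_I[n+1] | s_I[n], s_J[n]) / p(s_I[n+1] | s_I[n]) ]

in bits, the ordinal-symbol form of transfer entropy.  Computed over all
ordered channel pairs it yields a 23 x 23 directed matrix; thresholding its
entries gives the weighted directed brain network whose nodes are channels
and whose edge weights are STE values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import networkx as nx

from .defaults import CHANNEL_NAMES, N_CHANNELS, STE_THRESHOLD


@dataclass(frozen=True)
class STEConfig:
    """Estimator settings.

    ``embed_m``/``delay_tau`` define the ordinal patterns (m=3, tau=1 keeps
    6 symbols, well estimated at segment length); ``history_k``/``history_l``
    are the symbol-history lengths of the target and driver conditioning.
    """

    embed_m: int = 3
    delay_tau: int = 1
    history_k: int = 1
    history_l: int = 1
    log_base: float = 2.0

    def __post_init__(self):
        if self.embed_m < 2:
            raise ValueError("embed_m must be >= 2")
        if self.delay_tau < 1:
            raise ValueError("delay_tau must be >= 1")
        if self.history_k < 1 or self.history_l < 1:
            raise ValueError("history lengths must be >= 1")

    @property
    def n_symbols(self) -> int:
        return math.factorial(self.embed_m)


@dataclass
class SymbolSequence:
    """Ordinal-symbol series produced by :func:`symbolize`."""

    symbols: np.ndarray
    source_length: int
    config: STEConfig

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class STEMatrix:
    """Directed pairwise STE in bits; ``values[j, i]`` is STE(J -> I)."""

    values: np.ndarray
    channel_names: list

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("STE matrix must be square")
        self.values = v


@dataclass
class BrainNetwork:
    """Thresholded weighted directed graph over channels."""

    graph: nx.DiGraph
    threshold: float
    channel_names: list

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def density(self) -> float:
        n = self.graph.number_of_nodes()
        return self.n_edges / (n * (n - 1)) if n > 1 else 0.0


def _lehmer_rank(perm: np.ndarray) -> int:
    """Lexicographic rank of a permutation (0-based)."""
    m = len(perm)
    rank = 0
    for i in range(m):
        smaller = int(np.sum(perm[i + 1:] < perm[i]))
        rank += smaller * math.factorial(m - 1 - i)
    return rank


def _pattern_table(m: int) -> dict:
    return {p: _lehmer_rank(np.array(p)) for p in itertools.permutations(range(m))}


def symbolize(series: np.ndarray, cfg: STEConfig = STEConfig()) -> SymbolSequence:
    """Map each embedding window to its ordinal-pattern rank.

    The pattern of a window is the index permutation that sorts it in
    ascending order; equal values take earlier-index-first order (a stable
    sort), so constant windows map to the identity pattern.
    """
    x = np.asarray(series, dtype=float)
    m, tau = cfg.embed_m, cfg.delay_tau
    span = (m - 1) * tau
    if len(x) <= span:
        raise ValueError(f"series length {len(x)} too short for m={m}, tau={tau}")
    windows = np.lib.stride_tricks.sliding_window_view(x, span + 1)[:, ::tau]
    perms = np.argsort(windows, axis=1, kind="stable")
    # vectorized Lehmer rank
    ranks = np.zeros(len(perms), dtype=np.int64)
    for i in range(m):
        smaller = np.sum(perms[:, i + 1:] < perms[:, i:i + 1], axis=1)
        ranks += smaller * math.factorial(m - 1 - i)
    return SymbolSequence(symbols=ranks, source_length=len(x), config=cfg)


def _history_codes(sym: np.ndarray, length: int, n_symbols: int) -> np.ndarray:
    """Encode sliding symbol histories of given length as single integers.

    ``out[t]`` encodes ``(sym[t-length+1], ..., sym[t])`` for
    ``t >= length-1``; aligned so ``out[i]`` is the history ending at
    ``sym[i + length - 1]``.
    """
    code = sym[: len(sym) - length + 1].astype(np.int64).copy()
    for j in range(1, length):
        code = code * n_symbols + sym[j: len(sym) - length + 1 + j]
    return code


def symbolic_transfer_entropy(sym_j: SymbolSequence, sym_i: SymbolSequence,
                              cfg: STEConfig = None) -> float:
    """Plug-in STE(J -> I) in bits from joint symbol histograms.

    Zero-probability terms contribute nothing and the estimate is floored
    at zero.  When the driver history carries no information beyond the
    target's own history (e.g. J is I itself), every log ratio is exactly
    one and the result is exactly zero.
    """
    if cfg is None:
        cfg = sym_i.config
    if len(sym_j) != len(sym_i):
        raise ValueError("symbol sequences must have equal length")
    si = np.asarray(sym_i.symbols, dtype=np.int64)
    sj = np.asarray(sym_j.symbols, dtype=np.int64)
    k, l, ns = cfg.history_k, cfg.history_l, cfg.n_symbols
    hist_start = max(k, l)  # first n with full histories (histories end at n)
    if len(si) < hist_start + 2:
        raise ValueError("symbol sequences too short for the requested histories")

    ih_all = _history_codes(si, k, ns)  # ih_all[t] ends at si[t+k-1]
    jh_all = _history_codes(sj, l, ns)
    # histories ending at n = hist_start-1 ... len-2; future = si[n+1]
    n0 = hist_start - 1
    n1 = len(si) - 1
    ih = ih_all[n0 - (k - 1): n1 - (k - 1)]
    jh = jh_all[n0 - (l - 1): n1 - (l - 1)]
    fut = si[n0 + 1: n1 + 1]

    n_i = ns ** k
    n_j = ns ** l
    triple = (fut * n_i + ih) * n_j + jh
    c_fij = np.bincount(triple, minlength=ns * n_i * n_j).reshape(ns, n_i, n_j)
    c_ij = c_fij.sum(axis=0)          # (ih, jh)
    c_fi = c_fij.sum(axis=2)          # (fut, ih)
    c_i = c_fij.sum(axis=(0, 2))      # (ih,)
    total = c_fij.sum()

    f_idx, i_idx, j_idx = np.nonzero(c_fij)
    num = c_fij[f_idx, i_idx, j_idx].astype(float) * c_i[i_idx]
    den = c_ij[i_idx, j_idx].astype(float) * c_fi[f_idx, i_idx]
    te = float(np.sum(c_fij[f_idx, i_idx, j_idx] / total * np.log2(num / den)))
    if cfg.log_base != 2.0:
        te *= math.log(2.0) / math.log(cfg.log_base)
    return max(te, 0.0)


def ste_matrix(segment, cfg: STEConfig = STEConfig(),
               override_channels: bool = False) -> STEMatrix:
    """Pairwise STE over all ordered channel pairs of a segment.

    ``values[j, i]`` is STE from channel j (driver) to channel i (target);
    the diagonal is exactly zero.  Channel counts other than 23 are
    refused unless ``override_channels`` is set.
    """
    segment.require_standard(override=override_channels)
    n_ch = segment.n_channels
    syms = [symbolize(segment.data[ch], cfg) for ch in range(n_ch)]
    values = np.zeros((n_ch, n_ch))
    for j in range(n_ch):
        for i in range(n_ch):
            if i != j:
                values[j, i] = symbolic_transfer_entropy(syms[j], syms[i], cfg)
    names = list(CHANNEL_NAMES[:n_ch]) if n_ch <= len(CHANNEL_NAMES) \
        else [f"ch{i}" for i in range(n_ch)]
    return STEMatrix(values=values, channel_names=names)


def threshold_network(m: STEMatrix, threshold: float = STE_THRESHOLD) -> BrainNetwork:
    """Keep directed edges whose STE weight is at least ``threshold``.

    All channel nodes are retained even when isolated, so graphs from
    different segments are directly comparable.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = nx.DiGraph()
    names = m.channel_names
    g.add_nodes_from(names)
    v = m.values
    for j in range(v.shape[0]):
        for i in range(v.shape[1]):
            if i != j and v[j, i] >= threshold:
                g.add_edge(names[j], names[i], weight=float(v[j, i]))
    return BrainNetwork(graph=g, threshold=threshold, channel_names=list(names))
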