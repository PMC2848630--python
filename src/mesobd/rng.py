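"""Seeded random variate source for the simulator.

A :class:`RandomStream` is the single source of randomness of a simulation
run: identical seed, mode and call sequence reproduce the variate stream
bit for bit.  Two modes are supported:

``on_demand``
    every variate is drawn from the underlying PCG64 generator when asked
    for (the default).

``precomputed_list``
    two fixed-size lists (single-precision uniforms and double-precision
    standard normals) are filled once and then consumed cyclically.  When a
    list is exhausted it is split into equal sections, each section's
    internal order is shuffled, one section (round-robin) is replaced with
    fresh draws, and the list is reassembled.  This trades statistical
    quality for fewer generator invocations and is an explicit opt-in.

Exponential variates are always produced by inversion of a uniform draw,
so they work identically in both modes.
"""

from __future__ import annotations

import numpy as np

DEFAULT_LIST_SIZE = 250_000
DEFAULT_SECTIONS = 10

_TINY = np.finfo(float).tiny


class RandomStream:
    """Reproducible uniform / Gaussian / exponential variate source.

    Parameters
    ----------
    seed:
        Integer seed for the underlying PCG64 generator.
    mode:
        ``"on_demand"`` or ``"precomputed_list"``.
    list_size:
        Number of values held in each pre-computed list (list mode only).
    sections:
        Number of equal sections used by the shuffle-and-replace refresh.
    """

    def __init__(
        self,
        seed: int,
        mode: str = "on_demand",
        list_size: int = DEFAULT_LIST_SIZE,
        sections: int = DEFAULT_SECTIONS,
    ) -> None:
        if mode not in ("on_demand", "precomputed_list"):
            raise ValueError(f"unknown rng mode {mode!r}")
        if list_size <= 0 or sections <= 0 or list_size % sections != 0:
            raise ValueError("list_size must be a positive multiple of sections")
        self.seed = int(seed)
        self.mode = mode
        self.list_size = int(list_size)
        self.sections = int(sections)
        self._gen = np.random.default_rng(self.seed)
        if mode == "precomputed_list":
            self.uniform_list = self._gen.random(self.list_size, dtype=np.float32)
            self.gaussian_list = self._gen.standard_normal(self.list_size)
            self._ucur = 0
            self._gcur = 0
            self._u_next_section = 0
            self._g_next_section = 0

    # -- list maintenance -------------------------------------------------

    def _refresh(self, values: np.ndarray, which: str) -> np.ndarray:
        """Shuffle-and-replace an exhausted list; returns the new list."""
        n_sec = self.sections
        sec_len = self.list_size // n_sec
        parts = [values[i * sec_len : (i + 1) * sec_len].copy() for i in range(n_sec)]
        for part in parts:
            self._gen.shuffle(part)
        if which == "uniform":
            replaced = self._u_next_section
            parts[replaced] = self._gen.random(sec_len, dtype=np.float32)
            self._u_next_section = (replaced + 1) % n_sec
        else:
            replaced = self._g_next_section
            parts[replaced] = self._gen.standard_normal(sec_len)
            self._g_next_section = (replaced + 1) % n_sec
        return np.concatenate(parts)

    def _take_uniform(self, n: int) -> np.ndarray:
        out = np.empty(n)
        filled = 0
        while filled < n:
            if self._ucur >= self.list_size:
                self.uniform_list = self._refresh(self.uniform_list, "uniform")
                self._ucur = 0
            m = min(n - filled, self.list_size - self._ucur)
            out[filled : filled + m] = self.uniform_list[self._ucur : self._ucur + m]
            self._ucur += m
            filled += m
        return out

    def _take_gaussian(self, n: int) -> np.ndarray:
        out = np.empty(n)
        filled = 0
        while filled < n:
            if self._gcur >= self.list_size:
                self.gaussian_list = self._refresh(self.gaussian_list, "gaussian")
                self._gcur = 0
            m = min(n - filled, self.list_size - self._gcur)
            out[filled : filled + m] = self.gaussian_list[self._gcur : self._gcur + m]
            self._gcur += m
            filled += m
        return out

    # -- scalar draws ------------------------------------------------------

    def next_uniform(self) -> float:
        """Next uniform variate in [0, 1)."""
        if self.mode == "precomputed_list":
            return float(self._take_uniform(1)[0])
        return float(self._gen.random())

    def next_gaussian(self) -> float:
        """Next standard normal variate."""
        if self.mode == "precomputed_list":
            return float(self._take_gaussian(1)[0])
        return float(self._gen.standard_normal())

    def next_exponential(self, rate: float) -> float:
        """Exponential waiting time with the given rate (inversion method)."""
        if rate <= 0.0:
            raise ValueError(f"exponential rate must be > 0, got {rate}")
        u = self.next_uniform()
        if u == 0.0:
            u = _TINY
        return -np.log(u) / rate

    # -- batch draws (consume the same sources in order) -------------------

    def uniforms(self, n: int) -> np.ndarray:
        if self.mode == "precomputed_list":
            return self._take_uniform(int(n))
        return self._gen.random(int(n))

    def normals(self, shape) -> np.ndarray:
        if self.mode == "precomputed_list":
            n = int(np.prod(shape))
            return self._take_gaussian(n).reshape(shape)
        return self._gen.standard_normal(shape)

    def permutation(self, n: int) -> np.ndarray:
        """Deterministic random permutation of range(n)."""
        return self._gen.permutation(int(n))

    def shuffle(self, seq: list) -> None:
        """In-place Fisher-Yates shuffle of a Python list."""
        self._gen.shuffle(seq)

    def integers(self, low: int, high: int, size=None):
        return self._gen.integers(low, high, size=size)
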