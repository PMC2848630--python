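"""Voxel partition of the simulation volume for bimolecular partner search.

The cubic volume of side L is divided into ``n_v`` voxels per axis.  Every
free reactive site is registered in the voxel containing its world
position; during bimolecular resolution each site is paired only against
sites in its own voxel and the 26 neighbouring voxels.  This is complete as
long as every voxel side exceeds the largest binding radius, which is
checked at initialisation.

Voxel intervals are half-open with the +L/2 faces clamped into the last
voxel, so every in-volume point maps to exactly one voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SiteRef
from .rng import RandomStream

try:  # optional JIT for the inner neighbour scan
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is present in normal installs
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _scan_neighbours(sorted_codes, bi, bj, bk, n_v, periodic):
        """For every b site, locate all a sites in its 27-voxel block.

        ``sorted_codes`` are the a-side voxel codes in ascending order;
        returns (positions into the sorted order, b indices).  An
        occupancy bitmask rejects empty neighbour voxels without a search.
        """
        nb = bi.shape[0]
        na = sorted_codes.shape[0]
        one = np.uint64(1)
        nwords = (n_v * n_v * n_v + 63) >> 6
        mask = np.zeros(nwords, np.uint64)
        for i in range(na):
            c = sorted_codes[i]
            mask[c >> 6] |= one << np.uint64(c & 63)
        cap = 4 * nb + 64
        out_a = np.empty(cap, np.int64)
        out_b = np.empty(cap, np.int64)
        k = 0
        for t in range(nb):
            for di in range(-1, 2):
                ii = bi[t] + di
                if periodic:
                    if ii < 0:
                        ii += n_v
                    elif ii >= n_v:
                        ii -= n_v
                elif ii < 0 or ii >= n_v:
                    continue
                for dj in range(-1, 2):
                    jj = bj[t] + dj
                    if periodic:
                        if jj < 0:
                            jj += n_v
                        elif jj >= n_v:
                            jj -= n_v
                    elif jj < 0 or jj >= n_v:
                        continue
                    for dk in range(-1, 2):
                        kk = bk[t] + dk
                        if periodic:
                            if kk < 0:
                                kk += n_v
                            elif kk >= n_v:
                                kk -= n_v
                        elif kk < 0 or kk >= n_v:
                            continue
                        code = (ii * n_v + jj) * n_v + kk
                        if (mask[code >> 6] >> np.uint64(code & 63)) & one == 0:
                            continue
                        lo = 0
                        hi = na
                        while lo < hi:
                            mid = (lo + hi) >> 1
                            if sorted_codes[mid] < code:
                                lo = mid + 1
                            else:
                                hi = mid
                        pos = lo
                        while pos < na and sorted_codes[pos] == code:
                            if k >= cap:
                                cap *= 2
                                grown_a = np.empty(cap, np.int64)
                                grown_b = np.empty(cap, np.int64)
                                grown_a[:k] = out_a[:k]
                                grown_b[:k] = out_b[:k]
                                out_a = grown_a
                                out_b = grown_b
                            out_a[k] = pos
                            out_b[k] = t
                            k += 1
                            pos += 1
        return out_a[:k], out_b[:k]


class GridError(ValueError):
    pass


class OutOfVolumeError(GridError):
    pass


def validate_voxel_size(voxel_side: float, max_sigma: float) -> None:
    """Voxels must be strictly larger than the largest binding radius."""
    if voxel_side <= 0 or max_sigma < 0:
        raise GridError("voxel side and binding radius must be positive")
    if voxel_side <= max_sigma:
        raise GridError(
            f"voxel side {voxel_side:.4g} m is not larger than the largest "
            f"binding radius {max_sigma:.4g} m; define a larger voxel size "
            "(fewer voxels per axis)"
        )


@dataclass
class SiteEntry:
    """A free reactive site registered for partner search."""

    cluster_uid: int
    entity_uid: int
    ref: SiteRef
    site_type: str
    position: np.ndarray


class VoxelGrid:
    """Uniform cubic grid over the volume [-L/2, L/2]^3."""

    def __init__(self, L: float, n_v: int, periodic: bool = False):
        if L <= 0 or n_v < 1:
            raise GridError("need L > 0 and n_v >= 1")
        self.L = float(L)
        self.n_v = int(n_v)
        self.voxel_side = self.L / self.n_v
        self.periodic = bool(periodic)
        self._entries: list[SiteEntry] = []
        self._codes: np.ndarray = np.empty(0, dtype=np.int64)
        self._meta_for: int | None = None  # id() of the entries list the caches match
        self._type_map: dict[str, np.ndarray] = {}
        self._cluster_uids = np.empty(0, dtype=np.int64)

    # -- indexing ----------------------------------------------------------

    def voxel_index(self, p) -> tuple[int, int, int]:
        """Voxel (i, j, k) of an in-volume point; raises outside the cube."""
        p = np.asarray(p, dtype=float)
        half = self.L / 2.0
        eps = 1e-12 * self.L
        if np.any(p < -half - eps) or np.any(p > half + eps):
            raise OutOfVolumeError(f"point {p} outside the simulation volume")
        idx = np.floor((p + half) / self.voxel_side).astype(int)
        idx = np.clip(idx, 0, self.n_v - 1)
        return (int(idx[0]), int(idx[1]), int(idx[2]))

    def voxel_codes(self, positions: np.ndarray) -> np.ndarray:
        """Vectorised linear voxel codes i*n_v^2 + j*n_v + k."""
        half = self.L / 2.0
        eps = 1e-12 * self.L
        if positions.size and (
            np.any(positions < -half - eps) or np.any(positions > half + eps)
        ):
            raise OutOfVolumeError("site position outside the simulation volume")
        idx = np.floor((positions + half) / self.voxel_side).astype(np.int64)
        np.clip(idx, 0, self.n_v - 1, out=idx)
        return (idx[:, 0] * self.n_v + idx[:, 1]) * self.n_v + idx[:, 2]

    def neighbor_voxels(self, idx, periodic: bool | None = None) -> list[tuple[int, int, int]]:
        """The up-to-26 neighbours of a voxel (excluding the voxel itself)."""
        if periodic is None:
            periodic = self.periodic
        i, j, k = idx
        n = self.n_v
        out = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    a, b, c = i + di, j + dj, k + dk
                    if periodic:
                        cell = (a % n, b % n, c % n)
                        if cell != (i, j, k) and cell not in out:
                            out.append(cell)
                    else:
                        if 0 <= a < n and 0 <= b < n and 0 <= c < n:
                            out.append((a, b, c))
        return out

    # -- occupancy ---------------------------------------------------------

    def rebuild(self, entries: list[SiteEntry], codes: np.ndarray | None = None) -> None:
        """Re-register all free reactive sites after a movement step.

        ``codes`` may supply pre-computed voxel codes (e.g. from positions
        wrapped into the volume); otherwise they are derived from the
        entries' positions.
        """
        self._entries = entries
        if codes is not None:
            self._codes = codes
        elif entries:
            positions = np.array([e.position for e in entries])
            self._codes = self.voxel_codes(positions)
        else:
            self._codes = np.empty(0, dtype=np.int64)

    @property
    def entries(self) -> list[SiteEntry]:
        return self._entries

    def _site_meta(self):
        """Cached per-entry type index and cluster-uid arrays.

        Rebuilt only when a different entries list is registered (the
        engine reuses one list object while the site population is
        unchanged, so the cache survives ordinary movement steps).
        """
        if self._meta_for != id(self._entries):
            by_type: dict[str, list[int]] = {}
            uids = np.empty(len(self._entries), dtype=np.int64)
            for i, e in enumerate(self._entries):
                by_type.setdefault(e.site_type, []).append(i)
                uids[i] = e.cluster_uid
            self._type_map = {
                t: np.array(ix, dtype=np.int64) for t, ix in by_type.items()
            }
            self._cluster_uids = uids
            self._meta_for = id(self._entries)
        return self._type_map, self._cluster_uids

    def occupancy(self) -> dict[tuple[int, int, int], set]:
        """Voxel -> registered sites, in the documented mapping form."""
        occ: dict[tuple[int, int, int], set] = {}
        n = self.n_v
        for entry, code in zip(self._entries, self._codes):
            code = int(code)
            key = (code // (n * n), (code // n) % n, code % n)
            occ.setdefault(key, set()).add(
                (entry.cluster_uid, entry.entity_uid, entry.ref)
            )
        return occ

    # -- distances ---------------------------------------------------------

    def pair_distance(self, p: np.ndarray, q: np.ndarray) -> float:
        """Euclidean distance, minimum-image if the volume is periodic."""
        d = p - q
        if self.periodic:
            d = d - self.L * np.round(d / self.L)
        return float(np.linalg.norm(d))


def candidate_pairs(
    grid: VoxelGrid,
    rules,
    rng: RandomStream,
):
    """Ordered candidate site pairs for the bimolecular rules.

    Every unordered pair of registered sites whose types match a rule and
    whose voxels are identical or 27-neighbours is emitted exactly once.
    The order follows the voxel-sequential scheme: occupied voxels are
    processed in a shuffled order, each voxel pairing its sites against the
    not-yet-processed neighbourhood, with random tie-breaking within a
    voxel.  Sites of the same cluster are never paired.

    Returns a list of ``(SiteEntry, SiteEntry, rule)`` triples.
    """
    entries = grid.entries
    n = len(entries)
    if n == 0:
        return []
    codes = grid._codes
    n_v = grid.n_v

    occupied = np.unique(codes)
    perm = rng.permutation(len(occupied))
    rank_of = np.empty(len(occupied), dtype=np.int64)
    rank_of[perm] = np.arange(len(occupied))
    site_rank = rank_of[np.searchsorted(occupied, codes)]

    by_type, cluster_uids = grid._site_meta()

    # decompose codes for neighbour arithmetic
    ci = codes // (n_v * n_v)
    cj = (codes // n_v) % n_v
    ck = codes % n_v

    offsets = np.array(
        [
            (di, dj, dk)
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            for dk in (-1, 0, 1)
        ],
        dtype=np.int64,
    )
    # direct-addressed buckets win for small grids; binary search on the
    # sorted codes wins when the grid is much larger than the site count
    dense = n_v**3 <= 32 * n

    raw_a: list[np.ndarray] = []
    raw_b: list[np.ndarray] = []
    raw_rule: list[int] = []
    rules = [r for r in rules if r.order == 2]
    for r_idx, rule in enumerate(rules):
        ia = by_type.get(rule.site_a)
        ib = by_type.get(rule.site_b)
        if ia is None or ib is None or len(ia) == 0 or len(ib) == 0:
            continue
        codes_a = codes[ia]
        order_a = np.argsort(codes_a, kind="stable")
        sorted_codes_a = codes_a[order_a]
        if _HAVE_NUMBA:
            a_pos, b_pos = _scan_neighbours(
                sorted_codes_a, ci[ib], cj[ib], ck[ib], n_v, grid.periodic
            )
            raw_a.append(ia[order_a[a_pos]])
            raw_b.append(ib[b_pos])
            raw_rule.append(np.full(len(a_pos), r_idx, dtype=np.int64))
            continue
        # all 27 neighbour voxel codes of every b site at once
        bi = ci[ib][None, :] + offsets[:, 0][:, None]
        bj = cj[ib][None, :] + offsets[:, 1][:, None]
        bk = ck[ib][None, :] + offsets[:, 2][:, None]
        if grid.periodic:
            bi %= n_v
            bj %= n_v
            bk %= n_v
            valid = np.ones(bi.shape, dtype=bool)
        else:
            valid = (
                (bi >= 0) & (bi < n_v)
                & (bj >= 0) & (bj < n_v)
                & (bk >= 0) & (bk < n_v)
            )
        target = ((bi * n_v + bj) * n_v + bk)[valid]
        b_site = np.broadcast_to(ib, bi.shape)[valid]
        if dense:
            counts_dense = np.bincount(sorted_codes_a, minlength=n_v**3)
            starts_dense = np.concatenate(([0], np.cumsum(counts_dense)))
            cnt = counts_dense[target]
            lo = starts_dense[target]
        else:
            lo = np.searchsorted(sorted_codes_a, target, side="left")
            cnt = np.searchsorted(sorted_codes_a, target, side="right") - lo
        nz = cnt > 0
        if not np.any(nz):
            continue
        cnt = cnt[nz]
        lo = lo[nz]
        b_site = b_site[nz]
        total = int(cnt.sum())
        cum = np.cumsum(cnt) - cnt
        a_pos = np.repeat(lo, cnt) + (np.arange(total) - np.repeat(cum, cnt))
        raw_a.append(ia[order_a[a_pos]])
        raw_b.append(np.repeat(b_site, cnt))
        raw_rule.append(np.full(total, r_idx, dtype=np.int64))

    if not raw_a:
        return []
    A = np.concatenate(raw_a)
    B = np.concatenate(raw_b)
    R = np.concatenate(raw_rule)

    # drop intra-cluster pairs
    keep = cluster_uids[A] != cluster_uids[B]
    A, B, R = A[keep], B[keep], R[keep]
    if len(A) == 0:
        return []

    # deduplicate unordered pairs (same-type rules and small periodic grids
    # can discover a pair more than once)
    lo_i = np.minimum(A, B)
    hi_i = np.maximum(A, B)
    pair_id = (R * n + lo_i) * n + hi_i
    _, first = np.unique(pair_id, return_index=True)
    A, B, R = A[first], B[first], R[first]

    # voxel-sequential order: a pair is emitted when the earlier-ranked of
    # its two voxels is processed; random tie-break within a voxel
    key_rank = np.minimum(site_rank[A], site_rank[B])
    tie = rng.uniforms(len(A))
    order = np.lexsort((tie, key_rank))
    return [(entries[int(A[t])], entries[int(B[t])], rules[int(R[t])]) for t in order]


def brute_force_pairs(grid: VoxelGrid, rules, sigma_of) -> set:
    """All-pairs reference oracle: unordered pairs within sigma of a rule.

    ``sigma_of(rule)`` supplies the distance threshold.  Intended for
    validation against the voxel-mediated search.
    """
    entries = grid.entries
    out = set()
    for rule in rules:
        if rule.order != 2:
            continue
        sig = sigma_of(rule)
        for i in range(len(entries)):
            for j in range(len(entries)):
                if j <= i:
                    continue
                ei, ej = entries[i], entries[j]
                match = (
                    ei.site_type == rule.site_a and ej.site_type == rule.site_b
                ) or (ei.site_type == rule.site_b and ej.site_type == rule.site_a)
                if not match or ei.cluster_uid == ej.cluster_uid:
                    continue
                if grid.pair_distance(ei.position, ej.position) <= sig:
                    out.add((rule.id, min(i, j), max(i, j)))
    return out
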