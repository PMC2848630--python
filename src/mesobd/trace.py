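"""Plain-text trace output and post-hoc summarisation.

Traces are tab-separated text with a fixed nine-column grammar so that
user scripts (and :func:`trace_summary`) can parse them with standard
tools::

    iteration  time_s  kind  id  entities  position  orientation  features  count

* ``kind`` is ``C`` for a cluster record or ``N`` for an entity-count
  record; unused columns hold ``-``.
* cluster records list the member entities as ``user_id:uid`` pairs joined
  by ``;``; positions are the cluster centre of mass in nm (``x,y,z``),
  orientations the cluster quaternion ``w,x,y,z`` and features
  ``uid=name:state|name:state;...`` per member entity.
* count records carry the template id in ``id`` and the number of live
  instances in ``count``.

Records are emitted only for executed iterations whose index is divisible
by the output divisor.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

COLUMNS = [
    "iteration", "time_s", "kind", "id", "entities",
    "position", "orientation", "features", "count",
]

_NM = 1e-9


class TraceWriter:
    def __init__(self, spec, sink):
        from .modelio import OutputSpec

        self.spec = spec if spec is not None else OutputSpec()
        self.sink = sink
        self._wrote_header = False

    def _write(self, line: str):
        self.sink.write(line + "\n")

    def _header(self):
        self._write("# mesobd trace v1")
        self._write("# fields: " + " ".join(self.spec.fields))
        self._write("\t".join(COLUMNS))
        self._wrote_header = True

    def emit(self, sim) -> None:
        if not self._wrote_header:
            self._header()
        it = sim.iteration
        t = it * sim.cfg.dt
        selected = set(self.spec.selected)
        fields = self.spec.fields
        want_cluster_lines = any(
            f in fields for f in ("position", "orientation", "feature_state")
        )
        if want_cluster_lines:
            for c in sim.clusters.values():
                if selected and not any(e.template.id in selected for e in c.entities):
                    continue
                ents = ";".join(f"{e.template.id}:{e.uid}" for e in c.entities)
                pos = ori = feats = "-"
                if "position" in fields:
                    pos = ",".join(f"{x / _NM:.9g}" for x in c.com)
                if "orientation" in fields:
                    ori = ",".join(f"{x:.9g}" for x in c.orientation)
                if "feature_state" in fields:
                    feats = ";".join(
                        f"{e.uid}="
                        + "|".join(f"{k}:{v}" for k, v in e.feature_states.items())
                        for e in c.entities
                    )
                self._write(
                    f"{it}\t{t:.12g}\tC\t{c.uid}\t{ents}\t{pos}\t{ori}\t{feats}\t-"
                )
        if "entity_count" in fields:
            templates = self.spec.selected or tuple(sim.templates)
            for tid in templates:
                n = sim.entity_count(tid)
                self._write(f"{it}\t{t:.12g}\tN\t{tid}\t-\t-\t-\t-\t{n}")

    def flush(self):
        if not self._wrote_header:
            self._header()
        if hasattr(self.sink, "flush"):
            self.sink.flush()


def parse_trace(source) -> pd.DataFrame:
    """Parse a trace (path, file object or string) into a DataFrame."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(
        source, sep="\t", comment="#", dtype={"iteration": np.int64, "count": "object"}
    )
    return df


def _parse_features(cell: str) -> dict[int, dict[str, str]]:
    out: dict[int, dict[str, str]] = {}
    if not isinstance(cell, str) or cell == "-":
        return out
    for part in cell.split(";"):
        if not part:
            continue
        uid_str, _, feats = part.partition("=")
        fs = {}
        if feats:
            for kv in feats.split("|"):
                k, _, v = kv.partition(":")
                fs[k] = v
        out[int(uid_str)] = fs
    return out


def _parse_entities(cell: str) -> list[tuple[str, int]]:
    if not isinstance(cell, str) or cell == "-":
        return []
    out = []
    for part in cell.split(";"):
        if not part:
            continue
        tid, _, uid = part.rpartition(":")
        out.append((tid, int(uid)))
    return out


def trace_summary(source, query: dict) -> pd.Series:
    """Per-timepoint counts matching a predicate.

    Queries (dicts):

    * ``{"kind": "count", "template": "B"}`` — the entity-count records of
      one template.
    * ``{"kind": "feature", "template": "B", "feature": "rbound",
      "state": "2"}`` — entities of a template currently in a feature
      state (requires ``feature_state`` in the trace fields).
    * ``{"kind": "composition", "members": {"B": 1, "R": 2},
      "exact": False}`` — clusters containing at least (or, with
      ``exact``, precisely) the given member multiset.

    Returns a Series indexed by time (s).
    """
    kind = query.get("kind")
    if kind not in ("count", "feature", "composition"):
        raise ValueError(f"unknown query kind {kind!r}")
    df = parse_trace(source)
    if df.empty:
        return pd.Series(dtype=float)
    if kind == "count":
        sub = df[(df["kind"] == "N") & (df["id"] == query["template"])]
        return pd.Series(
            sub["count"].astype(int).values, index=sub["time_s"].values, name="count"
        )
    sub = df[df["kind"] == "C"]
    times = sorted(df["time_s"].unique())
    values = []
    for t in times:
        rows = sub[sub["time_s"] == t]
        n = 0
        for _, row in rows.iterrows():
            members = _parse_entities(row["entities"])
            if kind == "feature":
                feats = _parse_features(row["features"])
                for tid, uid in members:
                    if tid != query["template"]:
                        continue
                    if feats.get(uid, {}).get(query["feature"]) == query["state"]:
                        n += 1
            else:
                want = query["members"]
                have: dict[str, int] = {}
                for tid, _ in members:
                    have[tid] = have.get(tid, 0) + 1
                if query.get("exact", False):
                    if have == dict(want):
                        n += 1
                else:
                    if all(have.get(k, 0) >= v for k, v in want.items()):
                        n += 1
        values.append(n)
    return pd.Series(values, index=times, name="count")
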