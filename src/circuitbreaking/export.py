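"""Tab-separated and JSON export of graphs, characteristics and reports.

All tables carry a ``#``-prefixed metadata preamble (tool version, config
hash, free-form keys) above a single header row; floats are printed with 10
significant digits so reruns with the same configuration are byte-identical
and diffable.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .bifurcation import BifurcationScan
from .engine import Characteristic, FixedPointReport
from .graphs import CircuitCover, SCCDecomposition
from .model import InteractionGraph, RegulatoryModel
from .stability import StabilityReport


def write_tsv(df: pd.DataFrame, path, meta: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def edges_table(model: RegulatoryModel, graph: InteractionGraph) -> pd.DataFrame:
    rows = [
        {"source": model.names[j], "target": model.names[i], "sign": sign}
        for (j, i), sign in sorted(graph.edges.items())
    ]
    return pd.DataFrame(rows, columns=["source", "target", "sign"])


def sccs_table(model: RegulatoryModel, dec: SCCDecomposition) -> pd.DataFrame:
    rows = [
        {"scc": k, "vertex": model.names[v]}
        for k, comp in enumerate(dec.components)
        for v in comp
    ]
    return pd.DataFrame(rows, columns=["scc", "vertex"])


def circuits_table(
    model: RegulatoryModel, covers: Mapping[int, CircuitCover]
) -> pd.DataFrame:
    rows = []
    for k, cover in sorted(covers.items()):
        for ci, circ in enumerate(cover.circuits):
            rows.append(
                {
                    "scc": k,
                    "circuit": ci,
                    "vertices": ",".join(model.names[v] for v in circ),
                    "length": len(circ),
                }
            )
    return pd.DataFrame(rows, columns=["scc", "circuit", "vertices", "length"])


def cover_table(model: RegulatoryModel, covers: Mapping[int, CircuitCover]) -> pd.DataFrame:
    rows = []
    for k, cover in sorted(covers.items()):
        rows.append(
            {
                "scc": k,
                "cover": ",".join(model.names[v] for v in cover.cover),
                "m": len(cover.cover),
                "is_lvg": cover.is_lvg,
                "exact": cover.exact,
                "truncated": cover.truncated,
            }
        )
    return pd.DataFrame(rows, columns=["scc", "cover", "m", "is_lvg", "exact", "truncated"])


def characteristic_table(model: RegulatoryModel, char: Characteristic) -> pd.DataFrame:
    v1 = char.leading_vertex
    downstream = [v for v in char.scc if v != v1]
    rows = []
    for b in range(char.n_branches):
        for t, kappa in enumerate(char.grid):
            c = char.values[b, t]
            if not np.isfinite(c):
                continue
            row = {"kappa": kappa, "branch": b, "c": c}
            for v in downstream:
                row[model.names[v]] = char.states[b, t, v]
            rows.append(row)
    cols = ["kappa", "branch", "c"] + [model.names[v] for v in downstream]
    return pd.DataFrame(rows, columns=cols)


def fixed_points_table(
    model: RegulatoryModel,
    report: FixedPointReport,
    stability: Iterable[StabilityReport] | None = None,
) -> pd.DataFrame:
    stability = list(stability) if stability is not None else [None] * len(report.points)
    rows = []
    for idx, (fp, st) in enumerate(zip(report.points, stability)):
        row = {"point": idx, "residual": fp.residual}
        for i, name in enumerate(model.names):
            row[name] = fp.x[i]
        if st is not None:
            row["classification"] = st.classification
            row["max_re_lambda"] = st.max_real
            row["char_slope"] = st.char_slope
            row["prop1_slope"] = st.prop1_slope
            row["lvg_verdict"] = st.lvg_verdict
            row["eigenvalues"] = ";".join(
                f"{z.real:.10g}{z.imag:+.10g}j" for z in st.eigenvalues
            )
        row["provenance"] = ";".join(
            f"scc{k}:{kind}" + (f"@{kappa:.10g}" if kappa is not None else "")
            for (k, kind, kappa, _s, _l) in fp.provenance
        )
        rows.append(row)
    return pd.DataFrame(rows)


def scan_table(model: RegulatoryModel, scan: BifurcationScan) -> pd.DataFrame:
    rows = []
    for branch in scan.branches:
        for pt in branch.points:
            row = {
                scan.parameter: pt.param,
                "branch": branch.id,
                "classification": pt.classification,
                "max_re_lambda": pt.max_re,
            }
            for i, name in enumerate(model.names):
                row[name] = pt.x[i]
            rows.append(row)
    cols = [scan.parameter, "branch", "classification", "max_re_lambda"] + list(model.names)
    return pd.DataFrame(rows, columns=cols)


def events_json(scan: BifurcationScan) -> str:
    payload = []
    for e in scan.events:
        payload.append(
            {
                "type": e.kind,
                "parameter": scan.parameter,
                "value": float(e.param),
                "bracket": [float(e.bracket[0]), float(e.bracket[1])],
                "state": None if e.state is None else [float(v) for v in e.state],
                "frequency": None if e.frequency is None else float(e.frequency),
            }
        )
    return json.dumps(payload, indent=2, sort_keys=True)
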