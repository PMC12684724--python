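"""Readers and writers for every table and graph format in the pipeline.

All tabular I/O is CSV (UTF-8, ``.`` decimal, header mandatory; ``sep``
admits ``;`` and tab). Numeric cells are written with Python's shortest
round-trip ``repr``, so a write/read cycle reproduces values to at least
12 significant digits and identifiers exactly. Missing intensities are
*absent* (NaN in memory), never zero: zero-filling would bias downstream
mass isotopomer distributions.

Graph exchange uses Cytoscape JSON (``.cyjs``) with the standard
``elements.nodes[].data`` / ``elements.edges[].data`` layout.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    GraphIntegrityError,
    ParseError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Canonical columns of an annotation table.
ANNOTATION_COLUMNS = [
    "feature_id",
    "compound_name",
    "formula",
    "adduct",
    "ppm_error",
    "source",
    "score",
]

#: Fractional tolerance on the sum of a third-party MID row before rejection.
MID_SUM_TOLERANCE = 0.02

TRACER_STATES = frozenset({"labeled", "unlabeled"})


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Features (id, m/z, retention time) x per-sample intensities.

    ``data`` is indexed by ``feature_id`` with columns ``mz``, ``rt``
    (seconds) followed by one float column per sample; NaN means the
    intensity is absent for that sample.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise SchemaError(f"duplicate feature_id values: {list(dupes)}")
        for col in ("mz", "rt"):
            if col not in self.data.columns:
                raise SchemaError(f"feature table missing mandatory column '{col}'")
            vals = self.data[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValidationError(f"non-finite {col} values in feature table")
        if (self.data["mz"] <= 0).any():
            raise ValidationError("mz values must be positive")
        if (self.data["rt"] < 0).any():
            raise ValidationError("rt values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("mz", "rt")]

    def intensities(self, feature_id: str, sample_ids: list[str]) -> np.ndarray:
        """Per-sample intensity vector; NaN where absent."""
        return self.data.loc[feature_id, sample_ids].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def read_feature_table(path, sep: str = ",", rt_unit: str = "s") -> FeatureTable:
    """Read a feature-intensity CSV with columns feature_id, mz, rt, <samples>.

    Empty intensity cells become absent (NaN). ``rt_unit='min'`` converts
    retention times to seconds on the fly.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("feature_id", "mz", "rt"):
        if col not in raw.columns:
            raise SchemaError(f"feature table missing mandatory column '{col}'")
    sample_cols = [c for c in raw.columns if c not in ("feature_id", "mz", "rt")]
    out = pd.DataFrame(index=pd.Index(raw["feature_id"], name="feature_id"))

    def parse_column(col: str, allow_empty: bool) -> np.ndarray:
        # python float() is correctly rounded, so repr-written values
        # round-trip bit-exactly (pandas' fast parser can be 1 ulp off)
        values = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if not cell:
                if allow_empty:
                    values[i] = np.nan
                    continue
                raise ParseError(f"non-numeric {col} value at row {i + 2}")
            try:
                values[i] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric value '{cell}' in column '{col}' "
                    f"at row {i + 2}"
                ) from None
        return values

    for col in ("mz", "rt"):
        out[col] = parse_column(col, allow_empty=False)
    for col in sample_cols:
        out[col] = parse_column(col, allow_empty=True)
    if rt_unit == "min":
        out["rt"] = out["rt"] * 60.0
    elif rt_unit != "s":
        raise ValidationError(f"unknown rt_unit '{rt_unit}' (use 's' or 'min')")
    return FeatureTable(out)


def write_feature_table(table: FeatureTable, path, sep: str = ",") -> None:
    df = table.data.copy()
    # repr-based formatting preserves >= 17 significant digits
    for col in df.columns:
        df[col] = [("" if isinstance(v, float) and math.isnan(v) else repr(float(v)))
                   for v in df[col]]
    df.to_csv(path, sep=sep, index=True)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Sample metadata: experiment, condition, tracer state, replicate."""

    data: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        req = ["sample_id", "experiment", "condition", "tracer_state", "replicate"]
        for col in req:
            if col not in self.data.columns:
                raise SchemaError(f"sample sheet missing mandatory column '{col}'")
        if self.data["sample_id"].duplicated().any():
            dupes = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"]
            raise SchemaError(f"duplicate sample_id values: {list(dupes)}")
        bad = set(self.data["tracer_state"]) - TRACER_STATES
        if bad:
            raise ValidationError(
                f"tracer_state must be one of {sorted(TRACER_STATES)}, got {sorted(bad)}"
            )
        reps = self.data["replicate"].to_numpy(dtype=int)
        if (reps < 1).any():
            raise ValidationError("replicate indices must be positive integers")
        if not (self.data["tracer_state"] == "unlabeled").any():
            # detection/correction will fail later; flag now, error there
            self.warnings.append("no unlabeled samples in sheet")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def samples_for(self, condition: str, tracer_state: str,
                    experiment: str | None = None) -> list[str]:
        mask = (self.data["condition"] == condition) & (
            self.data["tracer_state"] == tracer_state
        )
        if experiment is not None:
            mask &= self.data["experiment"] == experiment
        return list(self.data.loc[mask, "sample_id"])

    def labeled_conditions(self) -> list[str]:
        mask = self.data["tracer_state"] == "labeled"
        return sorted(self.data.loc[mask, "condition"].unique())

    def __len__(self) -> int:
        return len(self.data)


def read_sample_sheet(path, sep: str = ",") -> SampleSheet:
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "experiment": str,
                                           "condition": str, "tracer_state": str})
    return SampleSheet(df.reset_index(drop=True))


def write_sample_sheet(sheet: SampleSheet, path, sep: str = ",") -> None:
    sheet.data.to_csv(path, sep=sep, index=False)


def validate_together(features: FeatureTable, samples: SampleSheet) -> None:
    """Cross-check that every feature-table sample column is declared."""
    unknown = set(features.sample_ids) - set(samples.sample_ids)
    if unknown:
        raise SchemaError(
            f"feature table references samples absent from sheet: {sorted(unknown)}"
        )


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

def read_annotation_table(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    for col in ("feature_id", "compound_name", "formula", "adduct", "ppm_error",
                "source"):
        if col not in df.columns:
            raise SchemaError(f"annotation table missing mandatory column '{col}'")
    if "score" not in df.columns:
        df["score"] = np.nan
    if not np.all(np.isfinite(df["ppm_error"].to_numpy(dtype=float))):
        raise ValidationError("non-finite ppm_error in annotation table")
    return df[ANNOTATION_COLUMNS]


def write_annotation_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# MID table
# ---------------------------------------------------------------------------

@dataclass
class MidRecord:
    """One node's mass isotopomer distribution in one experiment/condition.

    ``fractions`` is the vector M0..Mk on the probability simplex;
    ``enrichment`` is 1 - M0 (fraction of molecules carrying label).
    """

    node_id: str
    condition: str
    experiment: str
    fractions: np.ndarray
    fraction_sds: np.ndarray
    display_name: str = ""
    enrichment: float = 0.0
    quantification: float = 0.0
    quantification_sd: float = 0.0
    residual: float = 0.0
    annotated: bool = False

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.fraction_sds = np.asarray(self.fraction_sds, dtype=float)
        if self.fractions.shape != self.fraction_sds.shape:
            raise ValidationError(
                f"node '{self.node_id}': fractions and fraction_sds lengths differ"
            )
        if (self.fractions < 0).any():
            raise ValidationError(f"node '{self.node_id}': negative MID fraction")
        if (self.fraction_sds < 0).any():
            raise ValidationError(f"node '{self.node_id}': negative fraction sd")
        total = float(self.fractions.sum())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"node '{self.node_id}': MID sums to {total:.6f}, not 1"
            )
        self.enrichment = 1.0 - float(self.fractions[0])

    @property
    def length(self) -> int:
        return len(self.fractions)


@dataclass
class MIDTable:
    """A list of :class:`MidRecord`, the entry point of contextualization."""

    records: list[MidRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def node_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.node_id, None)
        return list(seen)

    def by_node(self) -> dict[str, list[MidRecord]]:
        out: dict[str, list[MidRecord]] = {}
        for r in self.records:
            out.setdefault(r.node_id, []).append(r)
        return out


_M_COL = re.compile(r"^M(\d+)$")
_SD_COL = re.compile(r"^SD_(\d+)$")


def read_mid_table(path, sep: str = ",") -> MIDTable:
    """Read a wide MID CSV (node_id, condition, experiment, M0..Mk, ...).

    Fraction rows summing within 2% of 1 are renormalized (third-party
    exports are commonly rounded); larger deviations are rejected. The
    ``annotated`` flag is inferred from a non-empty display_name when no
    explicit column is present.
    """
    df = pd.read_csv(path, sep=sep, dtype={"node_id": str, "condition": str,
                                           "experiment": str},
                     float_precision="round_trip")
    for col in ("node_id", "condition", "experiment"):
        if col not in df.columns:
            raise SchemaError(f"MID table missing mandatory column '{col}'")
    m_cols = sorted((c for c in df.columns if _M_COL.match(c)),
                    key=lambda c: int(_M_COL.match(c).group(1)))
    if not m_cols:
        raise SchemaError("MID table has no M0..Mk fraction columns")
    sd_cols = sorted((c for c in df.columns if _SD_COL.match(c)),
                     key=lambda c: int(_SD_COL.match(c).group(1)))
    records = []
    for idx, row in df.iterrows():
        fr = row[m_cols].to_numpy(dtype=float)
        fr = fr[~np.isnan(fr)]
        if (fr < 0).any():
            raise ValidationError(f"negative fraction in MID row '{row['node_id']}'")
        total = float(fr.sum())
        if abs(total - 1.0) > MID_SUM_TOLERANCE:
            raise ValidationError(
                f"MID row '{row['node_id']}' sums to {total:.4f}, "
                f"outside the {MID_SUM_TOLERANCE:.0%} tolerance"
            )
        if abs(total - 1.0) > 1e-9:  # bit-stability: leave exact rows alone
            fr = fr / total
        if sd_cols:
            sds = row[sd_cols].to_numpy(dtype=float)[: len(fr)]
            sds = np.nan_to_num(sds, nan=0.0)
        else:
            sds = np.zeros_like(fr)
        display = str(row.get("display_name", "") or "")
        if display.lower() == "nan":
            display = ""
        if "annotated" in df.columns and not pd.isna(row["annotated"]):
            annotated = str(row["annotated"]).strip().lower() in ("true", "1", "yes")
        else:
            annotated = bool(display)
        records.append(MidRecord(
            node_id=str(row["node_id"]),
            condition=str(row["condition"]),
            experiment=str(row["experiment"]),
            fractions=fr,
            fraction_sds=sds,
            display_name=display,
            quantification=float(row.get("quantification", 0.0) or 0.0),
            quantification_sd=float(row.get("quantification_sd", 0.0) or 0.0),
            residual=float(row.get("residual", 0.0) or 0.0),
            annotated=annotated,
        ))
    return MIDTable(records)


def write_mid_table(table: MIDTable, path, sep: str = ",") -> None:
    kmax = max((r.length for r in table.records), default=1)
    m_cols = [f"M{i}" for i in range(kmax)]
    sd_cols = [f"SD_{i}" for i in range(kmax)]
    rows = []
    for r in table.records:
        row: dict[str, object] = {
            "node_id": r.node_id,
            "display_name": r.display_name,
            "condition": r.condition,
            "experiment": r.experiment,
        }
        for i in range(kmax):
            row[m_cols[i]] = repr(float(r.fractions[i])) if i < r.length else ""
            row[sd_cols[i]] = repr(float(r.fraction_sds[i])) if i < r.length else ""
        row["enrichment"] = repr(float(r.enrichment))
        row["quantification"] = repr(float(r.quantification))
        row["quantification_sd"] = repr(float(r.quantification_sd))
        row["residual"] = repr(float(r.residual))
        row["annotated"] = str(r.annotated)
        rows.append(row)
    cols = (["node_id", "display_name", "condition", "experiment"]
            + m_cols + sd_cols
            + ["enrichment", "quantification", "quantification_sd", "residual",
               "annotated"])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Pathway graphs and context networks (Cytoscape JSON)
# ---------------------------------------------------------------------------

@dataclass
class PathwayGraph:
    """A reference pathway: nodes with a user-chosen matching identifier."""

    graph: nx.Graph
    id_attribute: str = "id"

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def match_key(self, node_id: str) -> str:
        return self.graph.nodes[node_id].get("match_key", "")


def read_pathway_cyjs(path, id_attribute: str = "id") -> PathwayGraph:
    """Load a Cytoscape JSON pathway; per-node matching key from data[id_attribute].

    A node lacking the attribute loads with an empty matching key (warning
    logged); an edge referencing an unknown node is a hard error.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    elements = doc.get("elements", doc)
    g = nx.Graph()
    for entry in elements.get("nodes", []):
        data = entry.get("data", {})
        nid = str(data["id"])
        if id_attribute in data:
            key = str(data[id_attribute])
        else:
            key = ""
            logger.warning("node '%s' lacks id attribute '%s'; empty matching key",
                           nid, id_attribute)
        g.add_node(nid, label=str(data.get("name", data.get("label", nid))),
                   match_key=key, **{k: v for k, v in data.items()
                                     if k not in ("id", "name", "label")})
    for entry in elements.get("edges", []):
        data = entry.get("data", {})
        src, dst = str(data["source"]), str(data["target"])
        for endpoint in (src, dst):
            if endpoint not in g:
                raise GraphIntegrityError(
                    f"edge references unknown node '{endpoint}'"
                )
        attrs = {k: v for k, v in data.items() if k not in ("source", "target", "id")}
        g.add_edge(src, dst, **attrs)
    return PathwayGraph(g, id_attribute=id_attribute)


def write_network_cyjs(network, path) -> None:
    """Serialize a context network (or pathway overlay) to Cytoscape JSON.

    Node data carries id, name, annotated flag, enrichment, quantification
    and the MID vector as a JSON list (floats round-trip via repr); edge
    data carries source, target and similarity. ``read_pathway_cyjs`` on
    the output reproduces the node and edge sets exactly.
    """
    nodes = []
    for node in network.nodes:
        data = {
            "id": node.node_id,
            "name": node.display_name or node.node_id,
            "annotated": bool(node.annotated),
            "enrichment": float(node.mean_enrichment),
            "quantification": float(node.mean_quantification),
            "mid": [float(x) for x in node.representative_mid],
        }
        nodes.append({"data": data})
    edges = []
    for e in network.edges:
        edges.append({"data": {
            "id": f"{e.node_a}--{e.node_b}",
            "source": e.node_a,
            "target": e.node_b,
            "similarity": float(e.similarity),
            "metric": e.metric,
        }})
    doc = {"elements": {"nodes": nodes, "edges": edges},
           "data": {"provenance": getattr(network, "provenance", {})}}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_msp(path) -> list[dict]:
    """Parse a minimal MSP spectral library (NAME, PRECURSORMZ, Num Peaks).

    Returns a list of dicts with keys name, precursor_mz, rt (0 when
    absent) and peaks (list of (mz, intensity) sorted by mz).
    """
    entries: list[dict] = []
    current: dict | None = None
    peaks_left = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if peaks_left > 0:
                parts = line.replace("\t", " ").split()
                if len(parts) < 2:
                    raise ParseError(f"malformed peak line {lineno}: '{line}'")
                current["peaks"].append((float(parts[0]), float(parts[1])))
                peaks_left -= 1
                if peaks_left == 0:
                    current["peaks"].sort(key=lambda p: p[0])
                    entries.append(current)
                    current = None
                continue
            if ":" not in line:
                raise ParseError(f"unparseable MSP line {lineno}: '{line}'")
            key, _, value = line.partition(":")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "NAME":
                current = {"name": value, "precursor_mz": 0.0, "rt": 0.0,
                           "peaks": []}
            elif current is None:
                raise ParseError(f"MSP field before NAME at line {lineno}")
            elif key in ("PRECURSORMZ", "PRECURSOR_MZ"):
                current["precursor_mz"] = float(value)
            elif key in ("RETENTIONTIME", "RT"):
                current["rt"] = float(value)
            elif key == "NUMPEAKS":
                peaks_left = int(value)
                if peaks_left == 0:
                    entries.append(current)
                    current = None
    if current is not None:
        raise ParseError("MSP file ended mid-entry (missing peaks)")
    return entries
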