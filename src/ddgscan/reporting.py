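"""Result tables, frequency distributions, class-count summaries and
per-residue attribute files for structure coloring.

The attribute-file writer emits the UCSF Chimera residue-attribute grammar
exactly: three header lines (``attribute:``, ``match mode:``, ``recipient:``)
followed by one TAB-separated line per residue (``\\t:<seqnum>.<chain>\\t<value>``),
so written files can be loaded for ddG heat-map coloring.  Percentages are
reported to one decimal with no renormalization.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stability import CLASS_LABELS, StabilityPrediction, classify_ddg


class ReportError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Class-count summaries
# ---------------------------------------------------------------------------

@dataclass
class ClassSummary:
    predictor: str
    counts: dict[str, int]
    percentages: dict[str, float]
    n: int


def classification_summary(predictions: list[StabilityPrediction],
                           predictor_field: str = "ddg_consensus") -> ClassSummary:
    """Counts and percentages per ddG band for one predictor field."""
    if not predictions:
        raise ReportError("classification_summary requires a non-empty input")
    counts = {label: 0 for label in CLASS_LABELS}
    n = 0
    for pred in predictions:
        value = getattr(pred, predictor_field)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        counts[classify_ddg(value)] += 1
        n += 1
    if n == 0:
        raise ReportError("no scorable predictions to summarize")
    percentages = {label: round(100.0 * c / n, 1) for label, c in counts.items()}
    return ClassSummary(predictor=predictor_field, counts=counts,
                        percentages=percentages, n=n)


def histogram(values, bin_width: float, value_range: tuple[float, float]):
    """Left-closed right-open bins over ``value_range``; values outside the
    range land in flagged underflow/overflow bins.  Returns
    (bin_edges, counts, underflow, overflow) with sum(counts)+under+over = n.
    """
    if bin_width <= 0:
        raise ReportError("bin_width must be positive")
    lo, hi = value_range
    n_bins = int(math.ceil((hi - lo) / bin_width - 1e-9))
    edges = [lo + k * bin_width for k in range(n_bins + 1)]
    counts = [0] * n_bins
    underflow = overflow = 0
    for v in values:
        if v < lo:
            underflow += 1
        elif v >= edges[-1]:
            overflow += 1
        else:
            counts[int((v - lo) / bin_width)] += 1
    return edges, counts, underflow, overflow


# ---------------------------------------------------------------------------
# Chimera attribute files
# ---------------------------------------------------------------------------

_ATTR_NAME = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


@dataclass
class AttributeMap:
    name: str
    values: dict[tuple[str, int], float] = field(default_factory=dict)
    comment: str = "color mapping: blue -> white -> red over [+max, -2] kcal/mol"

    def __post_init__(self):
        if not _ATTR_NAME.match(self.name):
            raise ReportError(f"illegal attribute name {self.name!r}")


def write_attribute_file(attr_map: AttributeMap, path: str | Path) -> None:
    """Emit the residue-attribute grammar exactly (one value per residue)."""
    if not attr_map.values:
        raise ReportError("attribute map is empty")
    lines = []
    if attr_map.comment:
        lines.append(f"# {attr_map.comment}")
    lines += [f"attribute: {attr_map.name}", "match mode: 1-to-1",
              "recipient: residues"]
    for (chain, seq_num) in sorted(attr_map.values):
        value = attr_map.values[(chain, seq_num)]
        lines.append(f"\t:{seq_num}.{chain}\t{value:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_attribute_file(path: str | Path) -> AttributeMap:
    """Inverse of :func:`write_attribute_file`."""
    name = None
    comment = ""
    values: dict[tuple[str, int], float] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            comment = line[1:].strip()
        elif line.startswith("attribute:"):
            name = line.split(":", 1)[1].strip()
        elif line.startswith(("match mode:", "recipient:")):
            continue
        elif line.startswith("\t:"):
            spec, value = line.strip().split("\t")
            seq, chain = spec.lstrip(":").split(".")
            values[(chain, int(seq))] = float(value)
    if name is None:
        raise ReportError(f"{path}: not an attribute file")
    return AttributeMap(name=name, values=values, comment=comment)


def attribute_map_from_predictions(predictions: list[StabilityPrediction],
                                   name: str, mode: str | None = None,
                                   reduce: str = "mean") -> AttributeMap:
    """Per-residue ddG attribute values from predictions (mean or min of the
    consensus ddG over the mutations at each residue)."""
    by_res: dict[tuple[str, int], list[float]] = {}
    for p in predictions:
        if mode is not None and p.mode != mode:
            continue
        if p.status != "ok" or math.isnan(p.ddg_consensus):
            continue
        by_res.setdefault((p.mutation.chain, p.mutation.position), []).append(
            p.ddg_consensus)
    if not by_res:
        raise ReportError("no scorable predictions for attribute mapping")
    agg = np.mean if reduce == "mean" else np.min
    values = {k: round(float(agg(v)), 3) for k, v in by_res.items()}
    return AttributeMap(name=name, values=values)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "chain", "position", "wt_aa", "mut_aa", "source", "mode",
    "ddg_esst", "ddg_signature", "ddg_consensus", "class_label",
    "secondary_structure", "accessibility", "n_lost", "n_gained",
    "n_retained", "status",
]


def predictions_to_dataframe(predictions: list[StabilityPrediction]) -> pd.DataFrame:
    rows = []
    for p in predictions:
        rows.append({
            "chain": p.mutation.chain,
            "position": p.mutation.position,
            "wt_aa": p.mutation.wt_aa,
            "mut_aa": p.mutation.mut_aa,
            "source": p.mutation.source,
            "mode": p.mode,
            "ddg_esst": None if p.ddg_esst is None else round(p.ddg_esst, 4),
            "ddg_signature": None if p.ddg_signature is None else round(p.ddg_signature, 4),
            "ddg_consensus": round(p.ddg_consensus, 4) if not math.isnan(p.ddg_consensus) else None,
            "class_label": p.class_label,
            "secondary_structure": p.environment.secondary_structure if p.environment else "",
            "accessibility": p.environment.accessibility if p.environment else "",
            "n_lost": p.n_lost, "n_gained": p.n_gained, "n_retained": p.n_retained,
            "status": p.status,
        })
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    return df.sort_values(["chain", "position", "mut_aa", "mode"],
                          kind="mergesort").reset_index(drop=True)


def write_results(predictions: list[StabilityPrediction], path: str | Path) -> None:
    """Write CSV plus a mirroring JSON (same rows, same order)."""
    path = Path(path)
    df = predictions_to_dataframe(predictions)
    try:
        df.to_csv(path.with_suffix(".csv"), index=False)
        records = json.loads(df.to_json(orient="records"))
        path.with_suffix(".json").write_text(json.dumps(records, indent=1) + "\n")
    except OSError as exc:
        raise ReportError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path).with_suffix(".csv"))
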