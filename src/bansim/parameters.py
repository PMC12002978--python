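"""The model's parameter table: 22 labelled inputs with uncertainty.

The budget-impact model is driven entirely by a table of 22 named
parameters, each a :class:`ParameterSpec` carrying a distribution family
(normal, BetaPERT, lognormal, or a degenerate point) and its
hyperparameters in native units. Labels are single letters A–H, J–W;
"I" is deliberately unused so labels stay alignable with the published
input table. Proportions are stored as fractions in [0, 1], never
percentages.

Tables are read and written as YAML (one record per label; see
``data/default_parameters.yaml`` for the schema and the packaged
defaults) and can be exported as a flat delimited table for
spreadsheets. Validation returns a list of findings rather than raising,
so a linter can report every problem at once.
"""

from __future__ import annotations

import importlib.resources
import io
from dataclasses import dataclass, replace

import pandas as pd
import yaml

from .distributions import betapert_mean

__all__ = [
    "LABELS",
    "PROPORTION_LABELS",
    "ParameterSpec",
    "ParameterTable",
    "Finding",
    "ParameterLoadError",
    "default_parameter_table",
    "load_parameter_table",
    "dump_parameter_table",
    "table_to_frame",
    "validate",
]

#: The 22 labels, in sampling order (alphabetical; "I" intentionally absent).
LABELS: tuple[str, ...] = tuple("ABCDEFGH") + tuple("JKLMNOPQRSTUVW")

FAMILIES = frozenset({"normal", "betapert", "lognormal", "point"})
UNITS = frozenset(
    {"visits/year", "proportion", "USD", "minutes", "USD/bed-hour", "USD/admission"}
)

#: Labels whose values are dimensionless fractions in [0, 1].
PROPORTION_LABELS = frozenset("CDEFGHJKLQRS")


@dataclass(frozen=True)
class ParameterSpec:
    """One model input: a label, a distribution family, hyperparameters.

    ``mean``/``sd`` apply to normal, lognormal, and point families;
    ``min``/``mode``/``max`` to BetaPERT (whose mean is derived, not
    stored).
    """

    label: str
    name: str
    dist_family: str
    units: str
    mean: float | None = None
    sd: float | None = None
    min: float | None = None
    mode: float | None = None
    max: float | None = None
    source: str = ""

    def central_value(self) -> float:
        """The distribution mean: stated mean, or the PERT closed form."""
        if self.dist_family == "betapert":
            return betapert_mean(self.min, self.mode, self.max)
        return float(self.mean)


@dataclass
class ParameterTable:
    """A complete set of 22 validated parameter specs, keyed by label."""

    specs: dict[str, ParameterSpec]
    metadata: str = ""

    def __getitem__(self, label: str) -> ParameterSpec:
        return self.specs[label]

    def replace_spec(self, label: str, **changes) -> "ParameterTable":
        """Return a copy of the table with one spec's fields replaced."""
        specs = dict(self.specs)
        specs[label] = replace(specs[label], **changes)
        return ParameterTable(specs=specs, metadata=self.metadata)

    def central_values(self) -> dict[str, float]:
        """Distribution mean of every parameter, keyed by label."""
        return {lbl: spec.central_value() for lbl, spec in self.specs.items()}


@dataclass(frozen=True)
class Finding:
    """One validation problem: which label, and what is wrong."""

    label: str
    message: str


class ParameterLoadError(ValueError):
    """Raised when a parameter-table source cannot be parsed or validated."""


def _validate_spec(spec: ParameterSpec) -> list[Finding]:
    out: list[Finding] = []
    lbl = spec.label

    if spec.dist_family not in FAMILIES:
        out.append(Finding(lbl, f"unknown distribution family {spec.dist_family!r}"))
        return out
    if spec.units not in UNITS:
        out.append(Finding(lbl, f"unknown units {spec.units!r}"))

    if spec.dist_family == "betapert":
        if spec.mean is not None or spec.sd is not None:
            out.append(Finding(lbl, "betapert takes min/mode/max, not mean/sd"))
        if spec.min is None or spec.mode is None or spec.max is None:
            out.append(Finding(lbl, "betapert requires min, mode and max"))
        else:
            if not (spec.min <= spec.mode <= spec.max):
                out.append(Finding(lbl, "betapert requires min <= mode <= max"))
            if not spec.min < spec.max:
                out.append(Finding(lbl, "betapert requires min < max"))
    else:
        if spec.min is not None or spec.mode is not None or spec.max is not None:
            out.append(
                Finding(lbl, f"{spec.dist_family} takes mean/sd, not min/mode/max")
            )
        if spec.mean is None:
            out.append(Finding(lbl, f"{spec.dist_family} requires a mean"))
        if spec.dist_family in ("normal", "lognormal"):
            if spec.sd is None:
                out.append(Finding(lbl, f"{spec.dist_family} requires an sd"))
            elif spec.sd < 0:
                out.append(Finding(lbl, f"sd must be >= 0, got {spec.sd}"))
            if spec.mean is not None and spec.mean <= 0:
                out.append(Finding(lbl, f"{spec.dist_family} mean must be > 0"))
        elif spec.dist_family == "point" and spec.sd not in (None, 0, 0.0):
            out.append(Finding(lbl, "point distribution cannot carry an sd"))

    if spec.units == "proportion" and not out:
        probe = spec.mode if spec.dist_family == "betapert" else spec.mean
        if probe is not None and not 0 <= probe <= 1:
            out.append(Finding(lbl, f"proportion central value {probe} outside [0, 1]"))
    return out


def validate(table: ParameterTable) -> list[Finding]:
    """Lint a table; an empty report means the sampler can consume it."""
    findings: list[Finding] = []
    present = set(table.specs)
    expected = set(LABELS)
    for missing in sorted(expected - present):
        findings.append(Finding(missing, "label missing from table"))
    for extra in sorted(present - expected):
        findings.append(Finding(extra, "unexpected label (not one of A-H, J-W)"))
    for lbl in sorted(present & expected):
        spec = table.specs[lbl]
        if spec.label != lbl:
            findings.append(Finding(lbl, f"spec label {spec.label!r} != key {lbl!r}"))
        findings.extend(_validate_spec(spec))
    return findings


# ---------------------------------------------------------------------------
# serialization

_NUMERIC_FIELDS = ("mean", "sd", "min", "mode", "max")


def _spec_from_record(label: str, rec: dict) -> ParameterSpec:
    if not isinstance(rec, dict):
        raise ParameterLoadError(f"parameter {label!r}: record must be a mapping")
    known = {"name", "dist", "units", "source", *_NUMERIC_FIELDS}
    unknown = set(rec) - known
    if unknown:
        raise ParameterLoadError(
            f"parameter {label!r}: unknown fields {sorted(unknown)}"
        )
    numbers: dict[str, float | None] = {}
    for fld in _NUMERIC_FIELDS:
        raw = rec.get(fld)
        if raw is None:
            numbers[fld] = None
            continue
        try:
            numbers[fld] = float(raw)
        except (TypeError, ValueError) as exc:
            raise ParameterLoadError(
                f"parameter {label!r}, field {fld!r}: not a number ({raw!r})"
            ) from exc
    return ParameterSpec(
        label=label,
        name=str(rec.get("name", "")),
        dist_family=str(rec.get("dist", "")),
        units=str(rec.get("units", "")),
        source=str(rec.get("source", "")),
        **numbers,
    )


def load_parameter_table(source: str | io.TextIOBase | dict) -> ParameterTable:
    """Parse and validate a YAML parameter table.

    ``source`` may be a YAML string, an open text stream, or an already
    parsed mapping. A table must carry all 22 labels unless it sets
    ``inherit: default``, in which case omitted labels are filled from
    the packaged defaults.

    Raises
    ------
    ParameterLoadError
        On malformed YAML, a malformed number (naming the label and
        field), a missing label, or any invariant violation — the
        message lists *all* validation findings, not just the first.
    """
    if isinstance(source, dict):
        doc = source
    else:
        text = source.read() if hasattr(source, "read") else source
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ParameterLoadError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ParameterLoadError("document must be a mapping with a 'parameters' key")

    records = doc["parameters"]
    if not isinstance(records, dict):
        raise ParameterLoadError("'parameters' must map labels to records")

    specs = {str(lbl): _spec_from_record(str(lbl), rec) for lbl, rec in records.items()}

    if doc.get("inherit") == "default":
        for lbl, spec in default_parameter_table().specs.items():
            specs.setdefault(lbl, spec)

    missing = sorted(set(LABELS) - set(specs))
    if missing:
        raise ParameterLoadError(f"missing parameter label(s): {', '.join(missing)}")

    table = ParameterTable(specs=specs, metadata=str(doc.get("metadata", "")))
    findings = validate(table)
    if findings:
        lines = "; ".join(f"{f.label}: {f.message}" for f in findings)
        raise ParameterLoadError(f"invalid parameter table — {lines}")
    return table


def dump_parameter_table(table: ParameterTable) -> str:
    """Serialize a table to YAML; ``load_parameter_table`` round-trips it."""
    records = {}
    for lbl in sorted(table.specs):
        spec = table.specs[lbl]
        rec: dict = {"name": spec.name, "dist": spec.dist_family}
        for fld in _NUMERIC_FIELDS:
            val = getattr(spec, fld)
            if val is not None:
                rec[fld] = val
        rec["units"] = spec.units
        if spec.source:
            rec["source"] = spec.source
        records[lbl] = rec
    return yaml.safe_dump(
        {"metadata": table.metadata, "parameters": records}, sort_keys=False
    )


def table_to_frame(table: ParameterTable) -> pd.DataFrame:
    """Flat one-row-per-label view for delimited export / spreadsheets."""
    rows = []
    for lbl in sorted(table.specs):
        spec = table.specs[lbl]
        rows.append(
            {
                "label": lbl,
                "name": spec.name,
                "dist": spec.dist_family,
                "mean": spec.mean,
                "sd": spec.sd,
                "min": spec.min,
                "mode": spec.mode,
                "max": spec.max,
                "units": spec.units,
                "source": spec.source,
            }
        )
    return pd.DataFrame(rows).set_index("label")


_DEFAULT_CACHE: ParameterTable | None = None


def default_parameter_table() -> ParameterTable:
    """The packaged default inputs (the published national model).

    Returns a fresh :class:`ParameterTable` each call (specs are frozen
    and shared); successive calls compare equal.
    """
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        ref = importlib.resources.files("bansim.data") / "default_parameters.yaml"
        _DEFAULT_CACHE = load_parameter_table(ref.read_text(encoding="utf-8"))
    return ParameterTable(
        specs=dict(_DEFAULT_CACHE.specs), metadata=_DEFAULT_CACHE.metadata
    )
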