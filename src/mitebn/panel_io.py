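"""Reading, validating and writing patient sIgE panel tables, plus DOT export.

A panel file is a delimited text table with one row per patient and the
header ``id, age, tIgE, Der f 1, ..., Der p 23`` (header matching is case-,
whitespace- and underscore-insensitive).  Concentrations are kU/L.  tIgE may
be missing (it is descriptive only); a missing or unparseable sIgE value is
treated as file corruption and rejected loudly, because the multiplex assay
always reports the complete component panel.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .catalog import COMPONENTS, canonical_component, normalize_header
from ._util import natural_key

logger = logging.getLogger(__name__)

_META_COLUMNS = ("id", "age", "tIgE")
_META_CANON = {"id": "id", "age": "age", "tige": "tIgE"}

MAX_AGE_YEARS = 150.0


class PanelFormatError(ValueError):
    """Raised when a panel file violates the format contract."""


class PatientRecord(NamedTuple):
    id: str
    age: float
    tIgE: float  # NaN when not measured
    sIgE: dict[str, float]


@dataclass
class PanelTable:
    """Validated cohort table with canonical column order.

    The backing frame has columns ``id, age, tIgE`` followed by the eleven
    components in catalog order.
    """

    df: pd.DataFrame
    components: tuple[str, ...] = field(default=COMPONENTS)

    def __post_init__(self) -> None:
        expected = list(_META_COLUMNS) + list(self.components)
        if list(self.df.columns) != expected:
            self.df = self.df.reindex(columns=expected)
        self.validate()

    def validate(self) -> None:
        df = self.df
        ids = df["id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise PanelFormatError(f"duplicate patient id(s): {sorted(set(dup))[:5]}")
        age = df["age"].to_numpy(dtype=float)
        if len(age):
            if np.isnan(age).any():
                bad = df.loc[np.isnan(age), "id"].iloc[0]
                raise PanelFormatError(f"missing/unparseable age for patient {bad!r}")
            if (age < 0).any() or (age >= MAX_AGE_YEARS).any():
                bad = df.loc[(age < 0) | (age >= MAX_AGE_YEARS), "id"].iloc[0]
                raise PanelFormatError(f"age out of range [0, {MAX_AGE_YEARS}) for patient {bad!r}")
        conc = df[list(self.components)].to_numpy(dtype=float)
        if conc.size:
            if np.isnan(conc).any():
                row = int(np.where(np.isnan(conc).any(axis=1))[0][0])
                raise PanelFormatError(
                    f"missing/unparseable sIgE value for patient {df['id'].iloc[row]!r}"
                )
            if (conc < 0).any():
                row = int(np.where((conc < 0).any(axis=1))[0][0])
                raise PanelFormatError(f"negative concentration for patient {df['id'].iloc[row]!r}")
        tige = df["tIgE"].to_numpy(dtype=float)
        if tige.size and (tige[~np.isnan(tige)] < 0).any():
            bad = df.loc[(df["tIgE"] < 0).fillna(False), "id"].iloc[0]
            raise PanelFormatError(f"negative tIgE for patient {bad!r}")

    @property
    def n(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[PatientRecord]:
        comps = list(self.components)
        values = self.df[comps].to_numpy(dtype=float)
        for i, (pid, age, tige) in enumerate(
            zip(self.df["id"], self.df["age"], self.df["tIgE"])
        ):
            yield PatientRecord(str(pid), float(age), float(tige), dict(zip(comps, values[i])))

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.df)


def read_panel(path: str | Path, delimiter: str | None = None) -> PanelTable:
    """Read and validate a panel CSV/TSV.

    Parameters
    ----------
    path:
        Input file. Must contain ``id``, ``age``, ``tIgE`` and all eleven
        component columns (any case/underscore spelling).
    delimiter:
        Field delimiter; default comma. Pass ``"\\t"`` for TSV.

    Raises
    ------
    PanelFormatError
        On a missing column (named in the message), duplicate patient id,
        negative concentration or unparseable value.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter or ",", dtype=str, keep_default_na=False)

    rename: dict[str, str] = {}
    seen: set[str] = set()
    for col in raw.columns:
        canon = _META_CANON.get(normalize_header(col)) or canonical_component(col)
        if canon is None:
            logger.warning("ignoring unrecognised column %r in %s", col, path.name)
            continue
        if canon in seen:
            raise PanelFormatError(f"duplicated column {canon!r}")
        seen.add(canon)
        rename[col] = canon
    raw = raw[list(rename)].rename(columns=rename)

    missing = [c for c in list(_META_COLUMNS) + list(COMPONENTS) if c not in raw.columns]
    if missing:
        raise PanelFormatError(f"missing required column(s): {', '.join(missing)}")

    def parse(col: str) -> pd.Series:
        text = raw[col].str.strip()
        return pd.to_numeric(text.mask(text == ""), errors="coerce")

    df = pd.DataFrame({"id": raw["id"].astype(str)})
    df["age"] = parse("age")
    df["tIgE"] = parse("tIgE")
    # a non-empty tIgE cell that fails to parse is corruption, not missingness
    bad_tige = (raw["tIgE"].str.strip() != "") & df["tIgE"].isna()
    if bad_tige.any():
        raise PanelFormatError(
            f"unparseable tIgE for patient {df.loc[bad_tige, 'id'].iloc[0]!r}"
        )
    for comp in COMPONENTS:
        df[comp] = parse(comp)
    return PanelTable(df)


def _format_number(value: float) -> str:
    """Serialize a concentration/age with at most 4 decimal places."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    text = f"{float(value):.4f}".rstrip("0").rstrip(".")
    return text if text else "0"


def write_panel(table: PanelTable, path: str | Path) -> None:
    """Write a panel table as canonical CSV (comma, UTF-8, '.' decimals).

    Numbers are serialized with at most four decimal places; the header is
    always ``id,age,tIgE,<components in catalog order>``.  The output is a
    canonical form: ``write(read(f))`` is byte-identical for files already
    in canonical form.
    """
    table.validate()
    path = Path(path)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    header = list(_META_COLUMNS) + list(table.components)
    writer.writerow(header)
    comps = list(table.components)
    for row in table.df.itertuples(index=False):
        d = dict(zip(table.df.columns, row))
        writer.writerow(
            [str(d["id"]), _format_number(d["age"]), _format_number(d["tIgE"])]
            + [_format_number(d[c]) for c in comps]
        )
    path.write_text(buf.getvalue(), encoding="utf-8")


def export_dag_dot(net_or_dag, path: str | Path) -> None:
    """Write a Graphviz DOT digraph for a DAG (or the DAG of a BayesNet).

    Node and edge statements are emitted in canonical (natural) order so the
    output is byte-identical across runs for the same graph.
    """
    dag = getattr(net_or_dag, "dag", net_or_dag)
    lines = ["digraph sensitization {"]
    for node in sorted(dag.nodes, key=natural_key):
        lines.append(f'  "{node}";')
    for u, v in sorted(dag.edges, key=lambda e: (natural_key(e[0]), natural_key(e[1]))):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
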