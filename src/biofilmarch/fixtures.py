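"""Packaged reference tables from the source study, and the classification
path over them.

Four tables ship as version-controlled, checksummed CSV data:

* ``table2`` — substratum coverage (%) of all 15 inoculated strains on
  the tesserae at initial time (t0) and after 10 days (t10), with flags
  for Chlorophyta and for the eight strains that survived.
* ``table3`` — per strain, the mean over the three architecture
  quantities of each aggregation operator (max / mean / weighted), before
  cross-strain rescaling.
* ``table4`` — the same means computed on the rescaled quantities; for a
  fixed operator the column is the strain's colonization index I_C.
* ``table5`` — the five-strain selection of table4 used to define the
  porous / intermediate / compact bands.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .indices import OPERATORS, classify_strain

FIXTURE_IDS = ("table2", "table3", "table4", "table5")

_OP_COLS = {"max": "op_max", "mean": "op_mean", "weighted": "op_weighted"}


@dataclass
class TableFixture:
    identifier: str
    data: pd.DataFrame


def _data_file(name: str) -> bytes:
    return (resources.files("biofilmarch") / "data" / name).read_bytes()


def load_fixture(identifier: str, verify: bool = True) -> TableFixture:
    """Load a packaged table by id, verifying its checksum.

    The CSVs carry the study's printed values verbatim; the checksum
    guards against silent edits of the packaged data.
    """
    if identifier not in FIXTURE_IDS:
        raise ValueError(f"unknown fixture {identifier!r}; known: {FIXTURE_IDS}")
    raw = _data_file(f"{identifier}.csv")
    if verify:
        expected = json.loads(_data_file("checksums.json"))[f"{identifier}.csv"]
        actual = hashlib.sha256(raw).hexdigest()
        if actual != expected:
            raise ValueError(f"fixture {identifier} failed checksum verification")
    import io

    df = pd.read_csv(io.BytesIO(raw))
    return TableFixture(identifier=identifier, data=df)


def classify_from_fixture(fixture: TableFixture) -> pd.DataFrame:
    """Apply the colonization-index classification to a fixture table.

    Valid for ``table4``/``table5``, whose operator columns are per-
    operator I_C values.  Returns one row per strain with the three I_C
    values, per-operator labels, and the majority label.
    """
    if fixture.identifier not in ("table4", "table5"):
        raise ValueError("classification applies to the rescaled tables (table4/table5)")
    rows = []
    for _, rec in fixture.data.iterrows():
        ic = {op: float(rec[col]) for op, col in _OP_COLS.items()}
        label, per_op, unanimous = classify_strain(ic)
        rows.append(
            {
                "strain": rec["strain"],
                **{f"ic_{op}": ic[op] for op in OPERATORS},
                **{f"label_{op}": per_op[op] for op in OPERATORS},
                "label": label,
                "operators_agree": unanimous,
            }
        )
    out = pd.DataFrame(rows)
    return out


def fixture_group_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Min/max I_C per architecture label group and per operator column."""
    rows = []
    for label, grp in classified.groupby("label"):
        for op in OPERATORS:
            rows.append(
                {
                    "label": label,
                    "operator": op,
                    "min_ic": float(grp[f"ic_{op}"].min()),
                    "max_ic": float(grp[f"ic_{op}"].max()),
                    "n_strains": len(grp),
                }
            )
    return pd.DataFrame(rows)
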