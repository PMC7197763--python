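"""Drug-gene interaction records: the tabular ingestion boundary.

One record corresponds to one curated drug-gene interaction row: the drug,
the gene, the interaction type (the protein's role in the reaction), the
action type (how the drug and protein act on each other) and a flag marking
major metabolizing enzymes.  Records arrive as TSV (header required) or JSON.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from typing import Optional

from .errors import FormatError
from .vocab import ROLE_BY_INTERACTION, ActionType, GeneRole, InteractionType

TSV_COLUMNS = ["drug_id", "drug_name", "gene_symbol", "interaction_type", "action_type", "major"]


@dataclass(frozen=True)
class DrugGeneRecord:
    drug_id: str
    drug_name: str
    gene_symbol: str
    interaction_type: Optional[InteractionType]
    action_type: Optional[ActionType]
    major: bool = False
    #: explicit role override; when absent the role is inferred from the
    #: interaction type (metabolism -> enzyme, transportation -> transporter,
    #: binding -> carrier).
    role: Optional[GeneRole] = None

    def __post_init__(self):
        if not self.gene_symbol:
            raise FormatError("gene_symbol must be non-empty")

    def resolved_role(self) -> GeneRole:
        if self.role is not None:
            return self.role
        if self.interaction_type is None:
            raise FormatError(
                f"record for {self.gene_symbol} has neither a role nor an interaction type"
            )
        return ROLE_BY_INTERACTION[self.interaction_type]


def _parse_enum(enum_cls, value, column, line_no):
    if value in ("", None):
        return None
    try:
        return enum_cls(value)
    except ValueError as exc:
        raise FormatError(f"line {line_no}: bad {column} value {value!r}") from exc


def _parse_bool(value, line_no):
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise FormatError(f"line {line_no}: bad major flag {value!r}")


def read_records_tsv(text: str) -> list:
    """Parse interaction records from TSV text (tab-separated, header required)."""
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    if reader.fieldnames is None or not set(TSV_COLUMNS) <= set(reader.fieldnames):
        missing = set(TSV_COLUMNS) - set(reader.fieldnames or [])
        raise FormatError(f"records TSV is missing required columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(reader, start=2):
        records.append(
            DrugGeneRecord(
                drug_id=row["drug_id"].strip(),
                drug_name=row["drug_name"].strip(),
                gene_symbol=row["gene_symbol"].strip(),
                interaction_type=_parse_enum(InteractionType, row["interaction_type"].strip(), "interaction_type", i),
                action_type=_parse_enum(ActionType, row["action_type"].strip(), "action_type", i),
                major=_parse_bool(row["major"], i),
                role=_parse_enum(GeneRole, (row.get("role") or "").strip(), "role", i),
            )
        )
    return records


def write_records_tsv(records) -> str:
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(TSV_COLUMNS + ["role"])
    for r in records:
        writer.writerow(
            [
                r.drug_id,
                r.drug_name,
                r.gene_symbol,
                r.interaction_type.value if r.interaction_type else "",
                r.action_type.value if r.action_type else "",
                "true" if r.major else "false",
                r.role.value if r.role else "",
            ]
        )
    return out.getvalue()


def read_records_json(text: str) -> list:
    """JSON equivalent of the TSV schema: a list of objects with the same keys."""
    try:
        rows = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"records JSON is malformed: {exc}") from exc
    if not isinstance(rows, list):
        raise FormatError("records JSON must be a list of objects")
    records = []
    for i, row in enumerate(rows):
        records.append(
            DrugGeneRecord(
                drug_id=row["drug_id"],
                drug_name=row["drug_name"],
                gene_symbol=row["gene_symbol"],
                interaction_type=_parse_enum(InteractionType, row.get("interaction_type"), "interaction_type", i),
                action_type=_parse_enum(ActionType, row.get("action_type"), "action_type", i),
                major=bool(row.get("major", False)),
                role=_parse_enum(GeneRole, row.get("role"), "role", i),
            )
        )
    return records
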