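"""Parse KEGG-style compound and enzyme flat files.

The two parsers here turn the raw KEGG dialects into the intermediate
containers the network builders consume:

* :func:`parse_compound_dictionary` reads a COMPOUND flat file (``ENTRY`` /
  ``NAME`` fields, records separated by ``///``) into a
  :class:`MetaboliteDictionary` mapping every normalized synonym to its
  ``C#####`` code.
* :func:`parse_ec_reactions` reads enzyme entries (flat-file records with an
  EC identifier and reaction equations, or a compact one-line-per-entry
  dialect) into :class:`ECReactionRecord` objects.
* :func:`build_ec_metabolite_map` resolves reaction participants against the
  dictionary and summarizes each EC number's metabolite usage — the
  "reactions_slim" content that the enzyme-network builder consumes.

Reaction direction is deliberately discarded: two activities are later linked
when they share a metabolite *either* as substrate or product, so substrates
and products are pooled per reaction.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO, Union

logger = logging.getLogger(__name__)

#: A well-formed KEGG compound code: C followed by exactly five digits.
CODE_PATTERN = re.compile(r"^C\d{5}$")

#: EC number: four dot-separated fields; trailing fields may be "-" for
#: partially classified activities (e.g. "2.7.1.-").
EC_PATTERN = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")

_ARROW_PATTERN = re.compile(r"<=>|<->|=>|<=|->|=")
_COEFF_PATTERN = re.compile(r"^(\d+|\d*n)\s+")
_BRACKET_PATTERN = re.compile(r"\s*\[(?:RN|CPD):[^\]]*\]")


class FlatFileParseError(ValueError):
    """Raised when a flat-file record violates the dialect.

    Carries the 1-based line number of the offending record.
    """

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def normalize_name(name: str) -> str:
    """Normalize a metabolite name: trim, collapse internal whitespace, case-fold.

    Idempotent: ``normalize_name(normalize_name(x)) == normalize_name(x)``.
    """
    return " ".join(name.split()).casefold()


@dataclass
class MetaboliteDictionary:
    """Synonym -> code lookup built from a COMPOUND flat file.

    ``entries`` maps each normalized name to exactly one code; several names
    (synonyms) may map to the same code. ``codes`` is the set of all codes
    seen, including entries that carried no NAME field.
    """

    entries: dict[str, str] = field(default_factory=dict)
    codes: set[str] = field(default_factory=set)

    def add(self, name: str, code: str) -> None:
        key = normalize_name(name)
        if not key:
            return
        existing = self.entries.get(key)
        if existing is not None and existing != code:
            logger.warning(
                "duplicate metabolite name %r maps to %s and %s; keeping %s",
                name, existing, code, existing,
            )
            return
        self.entries[key] = code

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ECReactionRecord:
    """One enzyme entry: an EC number and its reaction participant lists.

    ``reactions`` preserves file order; the first list is the "main"
    reaction. Each participant is a metabolite name or code, coefficients
    stripped, direction discarded.
    """

    ec: str
    reactions: list[list[str]] = field(default_factory=list)
    source_line: str = ""


@dataclass
class ECMetaboliteMap:
    """EC number -> set of metabolite codes ("reactions_slim" content)."""

    map: dict[str, set[str]] = field(default_factory=dict)
    provenance: str = "union"


def _as_lines(stream: Union[str, TextIO, Iterable[str]]) -> list[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    if isinstance(stream, io.TextIOBase) or hasattr(stream, "read"):
        return stream.read().splitlines()
    return [line.rstrip("\n") for line in stream]


def _split_records(lines: list[str]) -> list[tuple[int, list[str]]]:
    """Split flat-file lines into (first_line_number, record_lines) chunks.

    Records are delimited by ``///``; blank lines also delimit records in the
    compact dialect. Line numbers are 1-based.
    """
    records: list[tuple[int, list[str]]] = []
    current: list[str] = []
    start = 1
    for i, line in enumerate(lines, start=1):
        if line.strip() == "///" or not line.strip():
            if current:
                records.append((start, current))
                current = []
            start = i + 1
        else:
            if not current:
                start = i
            current.append(line)
    if current:
        records.append((start, current))
    return records


def _fields_of(record: list[str]) -> dict[str, list[str]]:
    """Collect KEGG flat-file fields: keyword at column 0, continuations indented."""
    fields: dict[str, list[str]] = {}
    keyword = None
    for line in record:
        if line[:1].strip():  # new field
            parts = line.split(None, 1)
            keyword = parts[0]
            value = parts[1] if len(parts) > 1 else ""
            fields.setdefault(keyword, []).append(value)
        elif keyword is not None:
            fields[keyword].append(line.strip())
    return fields


def parse_compound_dictionary(stream: Union[str, TextIO, Iterable[str]]) -> MetaboliteDictionary:
    """Parse a KEGG COMPOUND flat file into a :class:`MetaboliteDictionary`.

    Every synonym in a record's NAME field (semicolon-separated, possibly
    spanning continuation lines) maps, after normalization, to the record's
    ENTRY code. Records without a NAME field contribute only their code.

    Raises
    ------
    FlatFileParseError
        If a record lacks an ENTRY line; the error names the line offset.
    """
    mdict = MetaboliteDictionary()
    for start, record in _split_records(_as_lines(stream)):
        fields = _fields_of(record)
        if "ENTRY" not in fields:
            raise FlatFileParseError("compound record without ENTRY line", start)
        code = fields["ENTRY"][0].split()[0] if fields["ENTRY"][0].split() else ""
        if not CODE_PATTERN.match(code):
            raise FlatFileParseError(f"ENTRY value {code!r} is not a compound code", start)
        mdict.codes.add(code)
        names = " ".join(fields.get("NAME", []))
        for name in names.split(";"):
            mdict.add(name, code)
    return mdict


def resolve_metabolite(name: str, mdict: MetaboliteDictionary) -> str | None:
    """Resolve a metabolite name to its code; return ``None`` on a miss.

    Inputs already shaped like a code (``C`` + five digits) pass through
    unchanged. A miss is a value, never an error, and a code is never
    fabricated.
    """
    token = name.strip()
    if CODE_PATTERN.match(token):
        return token
    return mdict.entries.get(normalize_name(token))


def split_equation(equation: str) -> list[str] | None:
    """Pool the participants of one reaction equation, direction discarded.

    Splits on a directional arrow (``<=>``, ``=``, ``->`` ...) and on `` + ``,
    strips stoichiometric coefficients (``2 H2O`` -> ``H2O``; ``n`` counts
    too) and KEGG cross-reference brackets. Returns ``None`` when no arrow is
    found (the caller skips the reaction with a warning). Duplicates are
    removed, first occurrence kept.
    """
    equation = _BRACKET_PATTERN.sub("", equation)
    if not _ARROW_PATTERN.search(equation):
        return None
    participants: list[str] = []
    for side in _ARROW_PATTERN.split(equation):
        for part in side.split(" + "):
            part = _COEFF_PATTERN.sub("", part.strip()).strip()
            if part and part not in participants:
                participants.append(part)
    return participants


def _record_from_flatfile(fields: dict[str, list[str]], start: int, raw: str) -> ECReactionRecord:
    entry = fields["ENTRY"][0].split()
    ec = entry[1] if entry and entry[0].upper() == "EC" else (entry[0] if entry else "")
    if not EC_PATTERN.match(ec):
        raise FlatFileParseError(f"ENTRY value {ec!r} is not an EC number", start)
    reactions: list[list[str]] = []
    if "REACTION" in fields:
        text = " ".join(fields["REACTION"])
        for equation in text.split(";"):
            equation = equation.strip()
            if not equation:
                continue
            parts = split_equation(equation)
            if parts is None:
                logger.warning("EC %s: unparseable equation %r skipped", ec, equation)
            elif parts:
                reactions.append(parts)
    elif "SUBSTRATE" in fields or "PRODUCT" in fields:
        # No explicit equation: pool the substrate and product lists as one reaction.
        pooled: list[str] = []
        for kw in ("SUBSTRATE", "PRODUCT"):
            for chunk in " ".join(fields.get(kw, [])).split(";"):
                name = _BRACKET_PATTERN.sub("", chunk).strip()
                if name and name not in pooled:
                    pooled.append(name)
        if pooled:
            reactions.append(pooled)
    return ECReactionRecord(ec=ec, reactions=reactions, source_line=raw)


def _record_from_compact(record: list[str], start: int) -> ECReactionRecord:
    """Compact dialect: 'EC 2.7.1.1 ; equation ; equation' plus extra equation lines."""
    head, _, rest = record[0].partition(";")
    tokens = head.split()
    ec = tokens[1] if tokens and tokens[0].upper() == "EC" else (tokens[0] if tokens else "")
    if not EC_PATTERN.match(ec):
        raise FlatFileParseError(f"entry without EC identifier: {record[0]!r}", start)
    equations = [e for e in rest.split(";") if e.strip()]
    equations.extend(line for line in record[1:] if line.strip())
    reactions = []
    for equation in equations:
        parts = split_equation(equation)
        if parts is None:
            logger.warning("EC %s: unparseable equation %r skipped", ec, equation.strip())
        elif parts:
            reactions.append(parts)
    return ECReactionRecord(ec=ec, reactions=reactions, source_line=record[0])


def parse_ec_reactions(stream: Union[str, TextIO, Iterable[str]]) -> list[ECReactionRecord]:
    """Parse enzyme entries into one :class:`ECReactionRecord` per entry, in file order.

    Accepts full flat-file records (``ENTRY EC x.x.x.x`` with ``REACTION`` /
    ``SUBSTRATE`` / ``PRODUCT`` fields) and a compact one-entry-per-record
    dialect (``EC x.x.x.x ; A + B <=> C``). An entry with no EC identifier is
    a parse error; an unparseable equation is skipped with a warning.
    """
    records = []
    for start, chunk in _split_records(_as_lines(stream)):
        fields = _fields_of(chunk)
        if "ENTRY" in fields:
            records.append(_record_from_flatfile(fields, start, chunk[0]))
        else:
            records.append(_record_from_compact(chunk, start))
    return records


def build_ec_metabolite_map(
    records: list[ECReactionRecord],
    mdict: MetaboliteDictionary | None = None,
    mode: str = "union",
) -> ECMetaboliteMap:
    """Summarize reaction records into an EC -> metabolite-code map.

    mode="union" pools every reaction's resolved participants; mode="main"
    uses only the first-listed reaction of each EC (and, for duplicate ECs
    across records, only the first record). Unresolvable names are dropped
    with a logged count; ECs whose resulting set is empty are retained.
    """
    if mode not in ("union", "main"):
        raise ValueError(f"mode must be 'union' or 'main', got {mode!r}")
    ecmap: dict[str, set[str]] = {}
    unresolved = 0
    for record in records:
        duplicate = record.ec in ecmap
        if duplicate:
            logger.warning("duplicate EC %s: %s", record.ec,
                           "sets merged" if mode == "union" else "first record wins")
            if mode == "main":
                continue
        codes = ecmap.setdefault(record.ec, set())
        reactions = record.reactions if mode == "union" else record.reactions[:1]
        for participants in reactions:
            for name in participants:
                if mdict is not None:
                    code = resolve_metabolite(name, mdict)
                else:
                    code = name.strip() if CODE_PATTERN.match(name.strip()) else None
                if code is None:
                    unresolved += 1
                else:
                    codes.add(code)
    if unresolved:
        logger.warning("%d reaction participants could not be resolved to codes", unresolved)
    return ECMetaboliteMap(map=ecmap, provenance=mode)


# ---------------------------------------------------------------------------
# "reactions_slim" TSV dialect: column 1 = EC number, columns 2+ = codes.

def write_reactions_slim(ecmap: ECMetaboliteMap, path) -> None:
    with open(path, "w") as fh:
        for ec in sorted(ecmap.map):
            fh.write("\t".join([ec, *sorted(ecmap.map[ec])]) + "\n")


def read_reactions_slim(stream: Union[str, TextIO, Iterable[str]]) -> ECMetaboliteMap:
    ecmap: dict[str, set[str]] = {}
    for i, line in enumerate(_as_lines(stream), start=1):
        if not line.strip():
            continue
        ec, *codes = line.rstrip("\n").split("\t")
        if not EC_PATTERN.match(ec):
            raise FlatFileParseError(f"first column {ec!r} is not an EC number", i)
        ecmap.setdefault(ec, set()).update(c for c in codes if c)
    return ECMetaboliteMap(map=ecmap, provenance="file")


def write_metabolite_name_code(mdict: MetaboliteDictionary, path) -> None:
    """Write the two-column (name, code) equivalence list."""
    with open(path, "w") as fh:
        for name in sorted(mdict.entries):
            fh.write(f"{name}\t{mdict.entries[name]}\n")
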