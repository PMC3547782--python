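"""Streaming MDL SDF reader/writer with skip-and-continue error handling.

The reader splits a file on ``$$$$`` delimiters and performs only light
structural validation (counts line, V2000 dialect, ``M  END`` terminator,
atom/bond block shape).  A malformed record is reported as an
:class:`SdfError` token carrying the record index, and the stream continues;
chemistry-level failures (valence, atom typing) are left to the handler at
import time.  This contract keeps one corrupt record from poisoning a batch.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Union

_PROP_HEADER = re.compile(r">\s*<(?P<name>[^>]+)>")


@dataclass
class SdfRecord:
    index: int  # 0-based position in the file
    molblock: str
    properties: dict[str, str] = field(default_factory=dict)


@dataclass
class SdfError:
    index: int
    message: str


def parse_sdf(path: Union[str, Path]) -> Iterator[Union[SdfRecord, SdfError]]:
    """Yield ``SdfRecord`` or ``SdfError`` for each ``$$$$``-delimited record."""
    path = Path(path)
    with path.open("r", errors="replace") as fh:
        text = fh.read()
    yield from parse_sdf_text(text)


def parse_sdf_text(text: str) -> Iterator[Union[SdfRecord, SdfError]]:
    chunks = text.split("$$$$")
    # Material after the final $$$$ that is not blank is a truncated record.
    trailing = chunks.pop() if chunks else ""
    for index, chunk in enumerate(chunks):
        if index > 0:
            # strip only the newline following the previous record's $$$$ —
            # a blank molecule-name line is data
            if chunk.startswith("\r\n"):
                chunk = chunk[2:]
            elif chunk.startswith("\n"):
                chunk = chunk[1:]
        yield _parse_record(index, chunk)
    if trailing.strip():
        yield SdfError(len(chunks), "truncated final record (missing $$$$ terminator)")


def _parse_record(index: int, chunk: str) -> Union[SdfRecord, SdfError]:
    lines = chunk.split("\n")
    try:
        molblock_lines, prop_lines = _split_molblock(lines)
    except ValueError as exc:
        return SdfError(index, str(exc))
    molblock = "\n".join(molblock_lines) + "\n"
    return SdfRecord(index, molblock, _parse_properties(prop_lines))


def _split_molblock(lines: list[str]) -> tuple[list[str], list[str]]:
    if len(lines) < 4:
        raise ValueError("record shorter than a molblock header")
    counts = lines[3]
    if "V3000" in counts:
        raise ValueError("V3000 connection tables are not supported")
    try:
        n_atoms, n_bonds = int(counts[0:3]), int(counts[3:6])
    except (ValueError, IndexError):
        raise ValueError("unreadable counts line") from None
    end = next((i for i, l in enumerate(lines) if l.startswith("M  END")), None)
    if end is None:
        raise ValueError("missing M  END")
    # Shape check on the atom/bond blocks: a truncated or garbled block is a
    # record-level error here, before any chemistry is attempted.
    block = lines[4 : 4 + n_atoms + n_bonds]
    if len(block) < n_atoms + n_bonds or end < 4 + n_atoms + n_bonds:
        raise ValueError("atom/bond block shorter than declared counts")
    for line in lines[4 : 4 + n_atoms]:
        try:
            float(line[0:10]), float(line[10:20]), float(line[20:30])
        except (ValueError, IndexError):
            raise ValueError("unparseable atom block") from None
    return lines[: end + 1], lines[end + 1 :]


def _parse_properties(lines: list[str]) -> dict[str, str]:
    props: dict[str, str] = {}
    name = None
    value: list[str] = []
    for line in lines:
        header = _PROP_HEADER.match(line)
        if header:
            if name is not None:
                props[name] = "\n".join(value).strip()
            name, value = header.group("name").strip(), []
        elif name is not None:
            value.append(line)
    if name is not None:
        props[name] = "\n".join(value).strip()
    return props


def write_record(fh, molblock: str, properties: dict[str, str]) -> None:
    """Append one SDF record (molblock + SD tags + terminator) to ``fh``."""
    fh.write(molblock.rstrip("\n") + "\n")
    for key, val in properties.items():
        fh.write(f">  <{key}>\n{val}\n\n")
    fh.write("$$$$\n")
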