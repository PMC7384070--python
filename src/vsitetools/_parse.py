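"""Low-level line scanning shared by the force-field and topology readers.

GROMACS parameter and topology files are whitespace-delimited text with
``;`` comments, ``[ section ]`` headers, and a small preprocessor
(``#include``, ``#define``, ``#ifdef``).  This module turns a file into a
stream of cleaned content lines tagged with their origin so higher layers
can report precise error locations.

Preprocessor scope is deliberately small: ``#define`` performs simple
token-for-token substitution (enough for parameter macros like
``gb_15``-style defines), and ``#ifdef`` blocks take the branch for the
symbol being *undefined* unless the files themselves defined it, with a
warning.  A full cpp-style expansion is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

from .errors import FileFormatError

log = logging.getLogger(__name__)


@dataclass
class Line:
    """One cleaned content line and where it came from."""

    path: Optional[Path]
    lineno: int
    text: str

    @property
    def where(self) -> str:
        name = str(self.path) if self.path is not None else "<text>"
        return f"{name}:{self.lineno}"

    @property
    def fields(self) -> list[str]:
        return self.text.split()


class LineReader:
    """Iterate content lines of GROMACS-style text, following includes.

    Parameters
    ----------
    resolve_includes:
        When true, ``#include`` targets are opened relative to
        ``include_root`` (or the including file's directory) and a missing
        target is a fatal :class:`FileFormatError`.  When false the target
        is only recorded in :attr:`includes_seen` — molecule topologies
        routinely include force-field files that are not co-located.
    """

    def __init__(self, resolve_includes: bool = True,
                 include_root: Optional[Path] = None):
        self.defines: dict[str, str] = {}
        self.includes_seen: list[str] = []
        self.resolve_includes = resolve_includes
        self.include_root = include_root

    def read_path(self, path: Path) -> Iterator[Line]:
        if not path.is_file():
            raise FileFormatError(f"file not found: {path}")
        yield from self.read_text(path.read_text(), path)

    def read_text(self, text: str, path: Optional[Path] = None) -> Iterator[Line]:
        cond_stack: list[bool] = []
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = line.split()
                directive = fields[0]
                if directive in ("#ifdef", "#ifndef"):
                    name = fields[1] if len(fields) > 1 else ""
                    defined = name in self.defines
                    if directive == "#ifdef" and not defined:
                        log.warning("%s: #ifdef %s taken as not defined",
                                    Line(path, lineno, line).where, name)
                    cond_stack.append(defined if directive == "#ifdef"
                                      else not defined)
                elif directive == "#else":
                    if not cond_stack:
                        raise FileFormatError(
                            f"{Line(path, lineno, line).where}: #else without #ifdef")
                    cond_stack[-1] = not cond_stack[-1]
                elif directive == "#endif":
                    if not cond_stack:
                        raise FileFormatError(
                            f"{Line(path, lineno, line).where}: #endif without #ifdef")
                    cond_stack.pop()
                elif not all(cond_stack):
                    continue
                elif directive == "#define":
                    if len(fields) >= 2:
                        self.defines[fields[1]] = " ".join(fields[2:])
                elif directive == "#undef":
                    if len(fields) >= 2:
                        self.defines.pop(fields[1], None)
                elif directive == "#include":
                    target = fields[1].strip('"<>') if len(fields) > 1 else ""
                    self.includes_seen.append(target)
                    if self.resolve_includes:
                        root = self.include_root or (path.parent if path else Path("."))
                        inc = root / target
                        if not inc.is_file():
                            raise FileFormatError(
                                f"{Line(path, lineno, line).where}: "
                                f"include file not found: {inc}")
                        yield from self.read_path(inc)
                else:
                    log.debug("ignoring preprocessor directive %r", directive)
                continue
            if not all(cond_stack):
                continue
            if self.defines:
                toks = [self.defines.get(t, t) for t in line.split()]
                line = " ".join(toks)
            yield Line(path, lineno, line)


def section_name(line: Line) -> Optional[str]:
    """Return the lower-cased section name if *line* is ``[ name ]``, else None."""
    t = line.text
    if t.startswith("[") and t.endswith("]"):
        return t[1:-1].strip().lower()
    return None


def parse_float(token: str, line: Line) -> float:
    try:
        return float(token)
    except ValueError:
        raise FileFormatError(
            f"{line.where}: cannot parse {token!r} as a number") from None


def parse_int(token: str, line: Line) -> int:
    try:
        return int(token)
    except ValueError:
        raise FileFormatError(
            f"{line.where}: cannot parse {token!r} as an integer") from None
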