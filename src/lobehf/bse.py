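"""Reader/writer for Gaussian-dialect basis set text (Basis Set Exchange style).

The accepted grammar is the block format used by the Gaussian program and by
the Basis Set Exchange download pages::

    ****
    H     0
    S   6   1.00
          0.3552322122E+02       0.9163596281E-02
          ...
    ****

Shell types ``S``, ``P`` and combined ``SP`` are supported; ``SP`` rows carry
one exponent and two coefficients (s and p).  Anything beyond p shells is
rejected: this package implements minimal bases only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReferenceShell", "BasisParseError", "parse_basis_text", "format_basis_text"]


@dataclass
class ReferenceShell:
    """One contracted shell of the reference (Slater-fit) basis.

    For p shells the primitives are Cartesian Gaussians ``x * exp(-a r^2)``
    sharing exponents across the three components.  Coefficients apply to
    *normalized* primitives, and the contraction itself is normalized to
    unit self-overlap.
    """

    element: str
    label: str  # "1s", "2s", "2p"
    exponents: np.ndarray
    coefficients: np.ndarray
    zeta: float | None = None   # Slater exponent, if the shell is a refit

    def __post_init__(self) -> None:
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.exponents.shape != self.coefficients.shape:
            raise ValueError("exponent/coefficient length mismatch")
        if np.any(self.exponents <= 0):
            raise ValueError("non-positive exponent in reference shell")

    @property
    def is_p(self) -> bool:
        return self.label.endswith("p")

    @property
    def n_primitives(self) -> int:
        return len(self.exponents)


class BasisParseError(ValueError):
    """Malformed basis text; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _shell_labels(element_blocks: list[str]) -> list[str]:
    # minimal-basis principal quantum numbers by block order per angular momentum
    counts = {"s": 0, "p": 0}
    labels = []
    for t in element_blocks:
        counts[t] += 1
        n = counts[t] + (1 if t == "p" else 0)
        labels.append(f"{n}{t}")
    return labels


def parse_basis_text(text: str) -> dict[str, list[ReferenceShell]]:
    """Parse Gaussian-dialect basis text into per-element shell lists.

    Returns a dict ``element -> [ReferenceShell, ...]`` in file order, with
    shell labels assigned by minimal-basis filling order (1s, 2s, 2p, ...).
    """
    lines = text.splitlines()
    # strip comments / blanks but remember original line numbers
    rows: list[tuple[int, str]] = []
    for i, raw in enumerate(lines, start=1):
        s = raw.split("!")[0].strip()
        if s:
            rows.append((i, s))
    if not rows:
        raise BasisParseError("empty basis text", 1)

    shells: dict[str, list[ReferenceShell]] = {}
    pos = 0
    n = len(rows)

    def expect_not_eof(what: str):
        if pos >= n:
            raise BasisParseError(f"unexpected end of file, expected {what}",
                                  rows[-1][0])

    while pos < n and rows[pos][1].startswith("****"):
        pos += 1
    while pos < n:
        lineno, header = rows[pos]
        parts = header.split()
        if len(parts) < 1 or not parts[0][0].isalpha():
            raise BasisParseError(f"expected element header, got {header!r}", lineno)
        element = parts[0].capitalize()
        pos += 1
        raw_shells: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
        while True:
            expect_not_eof("shell block or ****")
            lineno, line = rows[pos]
            if line.startswith("****"):
                pos += 1
                break
            hp = line.split()
            stype = hp[0].upper()
            if stype not in ("S", "P", "SP"):
                raise BasisParseError(f"unsupported shell type {hp[0]!r}", lineno)
            try:
                nprim = int(hp[1])
            except (IndexError, ValueError):
                raise BasisParseError(f"malformed shell header {line!r}", lineno)
            pos += 1
            exps, cs, cp = [], [], []
            for _ in range(nprim):
                expect_not_eof("primitive row")
                lineno, prow = rows[pos]
                try:
                    vals = [float(v.replace("D", "E").replace("d", "e"))
                            for v in prow.split()]
                except ValueError:
                    raise BasisParseError(
                        f"expected numeric primitive row, got {prow!r}",
                        lineno)
                want = 3 if stype == "SP" else 2
                if len(vals) != want:
                    raise BasisParseError(
                        f"expected {want} numbers in primitive row, got {len(vals)}",
                        lineno)
                exps.append(vals[0])
                cs.append(vals[1])
                if stype == "SP":
                    cp.append(vals[2])
                pos += 1
            raw_shells.append((stype, np.array(exps), np.array(cs), np.array(cp)))
        # expand SP and assign labels
        expanded: list[tuple[str, np.ndarray, np.ndarray]] = []
        for stype, exps, cs, cp in raw_shells:
            if stype == "SP":
                expanded.append(("s", exps, cs))
                expanded.append(("p", exps, cp))
            else:
                expanded.append((stype.lower(), exps, cs))
        labels = _shell_labels([t for t, _, _ in expanded])
        shells[element] = [
            ReferenceShell(element, lab, exps, coefs)
            for lab, (_, exps, coefs) in zip(labels, expanded)
        ]
    return shells


def format_basis_text(shells: dict[str, list[ReferenceShell]],
                      comment: str = "") -> str:
    """Serialize shells back to Gaussian-dialect text."""
    out = []
    if comment:
        for line in comment.splitlines():
            out.append(f"! {line}")
    out.append("****")
    for element, shl in shells.items():
        out.append(f"{element}     0")
        for sh in shl:
            out.append(f"{sh.label[-1].upper()}   {sh.n_primitives}   1.00")
            for a, c in zip(sh.exponents, sh.coefficients):
                out.append(f"      {a: .10E}       {c: .10E}")
        out.append("****")
    return "\n".join(out) + "\n"
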