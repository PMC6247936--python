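"""Independent brute-force evaluator for module definitions.

Works directly on the definition text with string splitting — no code
shared with the package's tokenizer/parser — and serves as the oracle for
completeness semantics.  Intended for ortholog (K-number) definitions,
whose identifiers contain no ``-`` or ``+`` characters.
"""

from __future__ import annotations


def _split_top(text: str, sep: str) -> list[str]:
    """Split on ``sep`` at parenthesis depth 0."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def _strip_outer_parens(text: str) -> str:
    text = text.strip()
    while text.startswith("(") and text.endswith(")"):
        depth = 0
        for i, ch in enumerate(text):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth == 0 and i < len(text) - 1:
                    return text  # outer parens do not wrap everything
        text = text[1:-1].strip()
    return text


def _chain_components(text: str) -> list[tuple[bool, str]]:
    """Split a +/- chain at depth 0 into (required, component) pairs."""
    comps: list[tuple[bool, str]] = []
    depth = 0
    required = True
    cur: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if depth == 0 and ch in "+-" and not (ch == "-" and text[i : i + 2] == "--" and not cur):
            if cur:
                comps.append((required, "".join(cur)))
                cur = []
                required = ch == "+"
                i += 1
                continue
            if ch == "-":  # leading optional marker
                required = False
                i += 1
                continue
        cur.append(ch)
        i += 1
    comps.append((required, "".join(cur)))
    return comps


def satisfied(expr: str, genes: set[str]) -> bool:
    """Whether a (sub)expression is satisfied by a set of identifiers."""
    expr = _strip_outer_parens(expr)
    if expr == "--":
        return True
    parts = _split_top(expr, " ")
    if len(parts) > 1:
        return all(satisfied(p, genes) for p in parts if p.strip())
    parts = _split_top(expr, ",")
    if len(parts) > 1:
        return any(satisfied(p, genes) for p in parts)
    comps = _chain_components(expr)
    if len(comps) > 1 or not comps[0][0]:
        return all(satisfied(c, genes) for req, c in comps if req)
    return expr in genes


def mcf_pair(definition: str, genes: set[str]) -> tuple[int, int]:
    """(satisfied, total) over the non-gap top-level blocks."""
    blocks = [b for b in _split_top(definition.strip(), " ") if b.strip()]
    blocks = [b for b in blocks if b != "--"]
    return (sum(1 for b in blocks if satisfied(b, genes)), len(blocks))


def leaves(definition: str) -> set[str]:
    """All identifiers occurring in a K-number definition."""
    import re

    return set(re.findall(r"K\d{5}", definition))
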