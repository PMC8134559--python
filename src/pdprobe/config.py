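"""Tiny ``key = value`` plain-text config format.

Used for surrogate specs, preprocessing settings and pipeline run
configs.  Lines are ``key = value``; blank lines and ``#`` comments are
ignored.  Values are parsed as int, float, bool (true/false) or left as
strings; the literal ``none`` parses to None.
"""

from __future__ import annotations


def _parse_value(text: str):
    text = text.strip()
    low = text.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", ""):
        return None
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    # quoted strings from repr()
    if len(text) >= 2 and text[0] == text[-1] and text[0] in "'\"":
        return text[1:-1]
    return text


def parse_config(text: str) -> dict:
    out: dict = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = _parse_value(value)
    return out


def dump_config(items: dict) -> str:
    lines = []
    for key, val in items.items():
        if val is None:
            val = "none"
        lines.append(f"{key} = {val}")
    return "\n".join(lines) + "\n"
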