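"""Plain-text structural-integrity report."""

from __future__ import annotations

from ..model import IntegrityFinding, StructureGraph


def render_report(findings) -> str:
    findings = sorted(findings)
    lines = [f"{len(findings)} issues"]
    for f in findings:
        lines.append(f"[{f.kind.value}] {f.subject}: {f.detail}")
    return "\n".join(lines) + "\n"


def integrity_report(s: StructureGraph, path: str | None = None):
    """Return the structure's findings (sorted); optionally write the text file."""
    findings = sorted(s.findings)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(render_report(findings))
    return findings
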