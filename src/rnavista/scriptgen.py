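"""Snippet-based plot-script composition.

Every emitted plot script is assembled at run time from a central bin of
small code snippets (theme, data loading, one plot family, saving). A
master config lists the ordered analysis steps of each workflow kind;
per-step configs list the snippets each step needs, in order. Snippets
carry ``{{tag}}`` placeholders (thresholds, column names, file paths,
group colours) substituted at composition time; any tag left unresolved
is a build error. Users restyle every generated script at once by
editing a snippet (e.g. the theme), or one plot by editing its script.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

SNIPPET_DIR = Path(__file__).parent / "snippets"
TAG_RE = re.compile(r"\{\{([A-Za-z0-9_]+)\}\}")

# snippets shared across a workflow's combined script: emitted once at the top
SHARED_SNIPPETS = ("header", "theme")


class UnresolvedTagError(ValueError):
    """A composed script still contains an unsubstituted ``{{tag}}``."""


@dataclass
class SnippetBin:
    """The snippet bin plus master/per-step configs."""

    snippets: dict[str, str]
    master_config: dict[str, list[str]]     # workflow kind -> ordered steps
    step_configs: dict[str, list[str]]      # step -> ordered snippet names

    def validate(self) -> None:
        for step, names in self.step_configs.items():
            missing = [n for n in names if n not in self.snippets]
            if missing:
                raise KeyError(f"step {step!r} references unknown snippet(s) {missing}")
        for kind, steps in self.master_config.items():
            missing = [s for s in steps if s not in self.step_configs]
            if missing:
                raise KeyError(f"workflow {kind!r} lists unconfigured step(s) {missing}")


def load_snippet_bin(directory: str | Path | None = None) -> SnippetBin:
    """Load the shipped snippet bin (or a user-modified copy)."""
    directory = Path(directory) if directory else SNIPPET_DIR
    snippets = {p.stem: p.read_text() for p in sorted(directory.glob("*.tmpl"))}
    master = yaml.safe_load((directory / "master.yaml").read_text())
    steps = yaml.safe_load((directory / "steps.yaml").read_text())
    bin_ = SnippetBin(snippets=snippets, master_config=master, step_configs=steps)
    bin_.validate()
    return bin_


def substitute_tags(text: str, context: dict[str, object], step: str) -> str:
    """Replace every ``{{tag}}`` with str(context[tag]); error if any remain."""
    def _sub(m: re.Match) -> str:
        tag = m.group(1)
        if tag not in context:
            raise UnresolvedTagError(
                f"unresolved tag {{{{{tag}}}}} while composing step {step!r}")
        return str(context[tag])

    return TAG_RE.sub(_sub, text)


def compose_script(step: str, bin: SnippetBin, context: dict[str, object],
                   snippet_override: dict[str, str] | None = None) -> str:
    """Compose one step's standalone plot script from its snippets.

    ``snippet_override`` maps a snippet name in the step config to a
    replacement snippet name (used to swap a plot body for the
    empty-state snippet when there is nothing to draw).
    """
    if step not in bin.step_configs:
        raise KeyError(f"step {step!r} not present in any per-step config")
    names = [snippet_override.get(n, n) if snippet_override else n
             for n in bin.step_configs[step]]
    text = "\n".join(bin.snippets[n] for n in names)
    return substitute_tags(text, context, step)


def compose_body(step: str, bin: SnippetBin, context: dict[str, object],
                 snippet_override: dict[str, str] | None = None) -> str:
    """The step's script without the shared header/theme snippets.

    Used to build the combined per-workflow script, where shared snippets
    appear exactly once at the top so that e.g. the font of every plot can
    be changed by editing one parameter.
    """
    names = [snippet_override.get(n, n) if snippet_override else n
             for n in bin.step_configs[step] if n not in SHARED_SNIPPETS]
    text = "\n".join(bin.snippets[n] for n in names)
    return substitute_tags(text, context, step)


def compose_workflow_script(blocks: list[str], bin: SnippetBin,
                            context: dict[str, object]) -> str:
    """One combined script regenerating every plot of a workflow instance."""
    shared = "\n".join(bin.snippets[n] for n in SHARED_SNIPPETS)
    shared = substitute_tags(shared, context, "<combined>")
    return "\n".join([shared] + blocks) + "\n"
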