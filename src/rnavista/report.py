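"""Self-contained HTML reports.

One report page per workflow instance plus an index. Each page embeds
every plot (base64 PNG, so the file is portable), with the description,
figure legend, methods and the generating script hidden inside
collapsible drop-downs, and a hyperlinked contents side bar with one
anchor per analysis step.
"""
from __future__ import annotations

import base64
from pathlib import Path

from jinja2 import Environment, BaseLoader

_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{{ title }}</title>
<style>
 body { font-family: sans-serif; margin: 0; display: flex; }
 nav { width: 270px; min-width: 270px; background: #1f2937; color: #eee;
       height: 100vh; overflow-y: auto; position: sticky; top: 0; padding: 1em; }
 nav a { color: #9fd3ff; text-decoration: none; display: block;
         padding: 2px 0; font-size: 0.85em; }
 main { padding: 1.5em 3em; max-width: 1000px; }
 section { margin-bottom: 2.5em; border-bottom: 1px solid #ddd; }
 img { max-width: 100%; border: 1px solid #eee; }
 details { margin: 0.3em 0; }
 summary { cursor: pointer; color: #146; font-size: 0.9em; }
 pre { background: #f6f8fa; padding: 0.8em; overflow-x: auto; font-size: 0.75em; }
 .empty { color: #a33; font-style: italic; }
 h1 { font-size: 1.4em; } h2 { font-size: 1.1em; }
</style>
</head>
<body>
<nav>
 <h2>{{ title }}</h2>
 <a href="index.html">&#8592; all workflows</a>
 <hr>
 {% for art in artifacts %}<a href="#{{ art.name }}">{{ art.title }}</a>
 {% endfor %}
</nav>
<main>
<h1>{{ title }}</h1>
<p>{{ subtitle }}</p>
{% for art in artifacts %}
<section id="{{ art.name }}">
 <h2>{{ art.title }}</h2>
 {% if art.empty %}<p class="empty">Nothing to show: {{ art.caption }}</p>{% endif %}
 {% if art.image_b64 %}<img src="data:image/png;base64,{{ art.image_b64 }}"
      alt="{{ art.title }}">{% endif %}
 <details><summary>Description &amp; interpretation</summary>
  <p>{{ art.description }}</p></details>
 <details><summary>Figure legend</summary><p>{{ art.caption }}</p></details>
 <details><summary>Methods</summary><p>{{ art.methods_text }}</p>
  <p>Data file: <code>{{ art.data_file }}</code>;
     script: <code>{{ art.script_file }}</code></p></details>
 <details><summary>Plot code</summary><pre>{{ art.script_text }}</pre></details>
</section>
{% endfor %}
</main>
</body>
</html>
"""

_INDEX = """<!DOCTYPE html>
<html lang="en">
<head><meta charset="utf-8"><title>Analysis report</title>
<style>body { font-family: sans-serif; margin: 3em; }
 li { margin: 0.4em 0; }</style></head>
<body>
<h1>Analysis report</h1>
<p>{{ n_instances }} workflow instance(s); plot types emitted per category:
{% for cat, n in counts.items() %} {{ cat }}: {{ n }};{% endfor %}</p>
<ul>
{% for inst in instances %}
 <li><a href="{{ inst.id }}.html">{{ inst.id }}</a> ({{ inst.kind }}
 {%- if inst.comparisons %}: {{ inst.comparisons | join(", ") }}{% endif %})
 &mdash; {{ inst.artifacts | length }} plots</li>
{% endfor %}
</ul>
</body>
</html>
"""

_env = Environment(loader=BaseLoader(), autoescape=True)


def render_report(manifest: dict, outdir: str | Path) -> list[Path]:
    """Render one HTML page per workflow instance plus an index page."""
    outdir = Path(outdir)
    pages: list[Path] = []
    page_tmpl = _env.from_string(_PAGE)
    for inst in manifest["instances"]:
        arts = []
        for a in inst["artifacts"]:
            art = dict(a)
            img = outdir / inst["id"] / a["image_file"]
            art["image_b64"] = (base64.b64encode(img.read_bytes()).decode()
                                if img.exists() else "")
            script = outdir / inst["id"] / a["script_file"]
            art["script_text"] = script.read_text() if script.exists() else ""
            arts.append(art)
        html = page_tmpl.render(
            title=inst["id"],
            subtitle=f"{inst['kind']} workflow"
                     + (f" — {', '.join(inst['comparisons'])}"
                        if inst["comparisons"] else ""),
            artifacts=arts)
        path = outdir / f"{inst['id']}.html"
        path.write_text(html)
        pages.append(path)
    index = _env.from_string(_INDEX).render(
        n_instances=len(manifest["instances"]),
        counts=manifest["emitted_type_counts"],
        instances=manifest["instances"])
    ipath = outdir / "index.html"
    ipath.write_text(index)
    pages.append(ipath)
    return pages
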