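"""Report rendering: text summary, machine-readable JSON, score chart.

The JSON report is the contract (schema-versioned, full precision,
byte-identical across reruns of the same inputs); the text summary
rounds scores to 2 decimals, and the PNG bar chart mirrors the class
color semantics: low in blue, increased in red, high in red with heavy
emphasis, with guide lines at the two classification thresholds.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zipfile
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

from .combine import CombinationParams, ScoreBundle
from .seqio import ProteinRecord, write_fasta

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class RunManifest:
    """Identity of one scoring run.

    The job identifier is a short hash of the run content (mode, inputs,
    position, parameters), so identical reruns are traceable to the
    same id and reports stay byte-identical; the wall-clock timestamp
    appears only in the human-readable summary.
    """

    job_id: str
    mode: str  # "compare" | "scan"
    input_names: tuple[str, ...]
    position: int | None = None
    params_provenance: str = "package defaults"

    @classmethod
    def create(
        cls,
        mode: str,
        inputs: Mapping[str, Sequence[ProteinRecord]],
        params: CombinationParams,
        position: int | None = None,
        params_provenance: str = "package defaults",
    ) -> "RunManifest":
        hasher = hashlib.sha1()
        hasher.update(mode.encode())
        hasher.update(str(position).encode())
        for name in sorted(inputs):
            hasher.update(name.encode())
            for rec in inputs[name]:
                hasher.update(rec.id.encode())
                hasher.update(rec.sequence.encode())
        hasher.update(repr(params).encode())
        return cls(
            job_id=f"job-{hasher.hexdigest()[:12]}",
            mode=mode,
            input_names=tuple(inputs),
            position=position,
            params_provenance=params_provenance,
        )


def _params_dict(params: CombinationParams) -> dict:
    return {
        "w_c": params.w_c, "w_a": params.w_a,
        "c_offset": params.c_offset, "c_divisor": params.c_divisor,
        "a_offset": params.a_offset, "a_divisor": params.a_divisor,
        "intercept": params.intercept, "floor": params.floor,
        "theta_low": params.theta_low, "theta_high": params.theta_high,
    }


def _render_txt(bundles: Sequence[ScoreBundle], manifest: RunManifest,
                params: CombinationParams) -> str:
    lines = [
        "Aggregation-propensity report",
        f"job id: {manifest.job_id}",
        f"generated: {datetime.now(timezone.utc).isoformat(timespec='seconds')}",
        f"mode: {manifest.mode}",
        f"inputs: {', '.join(manifest.input_names)}",
    ]
    if manifest.position is not None:
        lines.append(f"scanned position: {manifest.position}")
    lines += [
        f"parameters: {manifest.params_provenance}",
        f"class thresholds: low < {params.theta_low:g} <= increased <= {params.theta_high:g} < high",
        "",
        f"{'sequence':<40} {'score':>6} {'class':>10} {'delta':>7}  amyloid core",
    ]
    for b in bundles:
        delta = "" if b.delta is None else f"{b.delta:+.2f}"
        lines.append(
            f"{b.id:<40} {b.combined:>6.2f} {b.label:>10} {delta:>7}  "
            f"{b.core_sequence} @ {b.core_start}"
        )
    lines.append("")
    for b in bundles:
        if b.impact:
            lines.append(b.impact)
        if b.composition_floored:
            lines.append(
                f"note: {b.id} has no predicted disordered window; "
                "composition term floored at the scale minimum."
            )
        if b.clamped:
            lines.append(f"note: {b.id} combined score clamped at the floor.")
    return "\n".join(lines) + "\n"


def _render_png(bundles: Sequence[ScoreBundle], params: CombinationParams, path: Path) -> bool:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception as exc:  # pragma: no cover - plotting backend missing
        warnings.warn(f"score chart skipped: plotting unavailable ({exc})")
        return False
    colors = {"low": "tab:blue", "increased": "tab:red", "high": "firebrick"}
    fig, ax = plt.subplots(figsize=(max(4.0, 0.9 * len(bundles) + 2), 4.0))
    xs = range(len(bundles))
    heights = [b.combined for b in bundles]
    bar_colors = [colors[b.label] for b in bundles]
    edge = ["black" if b.label == "high" else "none" for b in bundles]
    widths = [2.0 if b.label == "high" else 0.0 for b in bundles]
    ax.bar(xs, heights, color=bar_colors, edgecolor=edge, linewidth=widths)
    ax.axhline(params.theta_low, color="grey", linestyle="--", linewidth=1)
    ax.axhline(params.theta_high, color="grey", linestyle=":", linewidth=1)
    ax.set_xticks(list(xs))
    ax.set_xticklabels([b.id for b in bundles], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("combined aggregation-propensity score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return True


def render_report(
    bundles: Sequence[ScoreBundle],
    manifest: RunManifest,
    out_dir: str | Path,
    params: CombinationParams | None = None,
    inputs: Mapping[str, Sequence[ProteinRecord]] | None = None,
    mutants: Sequence[ProteinRecord] | None = None,
    make_png: bool = True,
    make_zip: bool = False,
) -> list[Path]:
    """Write the output bundle; returns the list of files written.

    Always writes ``report.txt`` and ``report.json``; optionally
    ``scores.png`` (skipped with a warning when plotting fails), copies
    of the input FASTA files under ``inputs/``, a ``mutants.fasta`` for
    scan mode, and a ZIP of the whole bundle.
    """
    if not bundles:
        raise ValueError("at least one score bundle is required")
    params = params or CombinationParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    txt_path = out_dir / "report.txt"
    txt_path.write_text(_render_txt(bundles, manifest, params))
    written.append(txt_path)

    payload = {
        "schema_version": SCHEMA_VERSION,
        "job_id": manifest.job_id,
        "mode": manifest.mode,
        "position": manifest.position,
        "inputs": list(manifest.input_names),
        "params": _params_dict(params),
        "results": [b.to_dict() for b in bundles],
    }
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written.append(json_path)

    if make_png:
        png_path = out_dir / "scores.png"
        if _render_png(bundles, params, png_path):
            written.append(png_path)

    if inputs:
        input_dir = out_dir / "inputs"
        input_dir.mkdir(exist_ok=True)
        for name, records in inputs.items():
            path = input_dir / f"{Path(name).stem}.fasta"
            write_fasta(records, path)
            written.append(path)

    if mutants:
        mutants_path = out_dir / "mutants.fasta"
        write_fasta(mutants, mutants_path)
        written.append(mutants_path)

    if make_zip:
        zip_path = out_dir / f"{manifest.job_id}.zip"
        with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
            for f in written:
                zf.write(f, f.relative_to(out_dir))
        written.append(zip_path)
    return written
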