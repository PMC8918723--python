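"""QC aggregation and self-contained HTML report rendering.

Every number shown in the HTML comes from the :class:`QCBundle`; the
template layer computes nothing.  Each plotted table is also persisted
as a TSV sidecar next to the report.  Rendering is deterministic:
matplotlib's SVG hash salt is pinned, figures carry no creation date,
and timestamps/versions are injected from the bundle metadata rather
than sampled at render time.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

matplotlib.rcParams["svg.hashsalt"] = "metharc"

DEFAULT_FLANK = 2000
DEFAULT_BINS = 100
DEFAULT_MAX_FRAG = 600


@dataclass
class QCBundle:
    """All statistics feeding the report; JSON-serialisable."""

    metadata: dict = field(default_factory=dict)  # mode, chemistry, version, config echo
    trim: dict = field(default_factory=dict)
    alignment: dict = field(default_factory=dict)  # total, mapped, low_quality, duplicates, reported
    conversion: Optional[dict] = None
    overall_level: Optional[float] = None
    per_chromosome: dict = field(default_factory=dict)
    m_bias: Optional[list] = None           # records of mate, cycle, meth, unmeth, level
    size_hist_target: Optional[dict] = None  # {"lengths": [...], "counts": [...]}
    size_hist_spike: Optional[dict] = None
    size_note: Optional[str] = None
    tss_profile: Optional[dict] = None      # {"bin_center": [...], "level": [...]}
    tss_note: Optional[str] = None
    composition_before: dict = field(default_factory=dict)
    composition_after: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as out:
            json.dump(self.__dict__, out, indent=2, sort_keys=True, default=_np_safe)
            out.write("\n")

    @classmethod
    def from_json(cls, path) -> "QCBundle":
        with open(path) as fh:
            data = json.load(fh)
        bundle = cls()
        for key, value in data.items():
            setattr(bundle, key, value)
        return bundle


def _np_safe(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# statistics

def size_distribution(alignments, max_len: int = DEFAULT_MAX_FRAG
                      ) -> tuple[Optional[dict], Optional[dict], Optional[str]]:
    """1-bp fragment-size histograms for target DNA and spike-in controls.

    Single-end data has no fragment sizes; returns (None, None, note).
    Each fragment is counted once (from its mate-1 record).
    """
    target = np.zeros(max_len + 1, dtype=int)
    spike = np.zeros(max_len + 1, dtype=int)
    any_pe = False
    for aln in alignments:
        if not aln.paired or aln.mate != 1:
            continue
        any_pe = True
        flen = min(aln.fragment_len, max_len)
        (spike if aln.is_spike_in else target)[flen] += 1
    if not any_pe:
        return None, None, "single-end data: fragment sizes not available"
    def pack(arr):
        lengths = np.nonzero(arr)[0]
        return {"lengths": lengths.tolist(), "counts": arr[lengths].tolist()}
    return pack(target), pack(spike), None


def read_tss_bed(path) -> pd.DataFrame:
    """Parse a BED6 of transcript start sites (strand-aware)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6 or fields[5] not in "+-":
                raise ValueError(f"malformed BED6 line {lineno} in {path}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"malformed BED6 line {lineno} in {path}") from None
            rows.append((fields[0], start, end, fields[5]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def tss_profile(calls: pd.DataFrame, tss: pd.DataFrame,
                flank: int = DEFAULT_FLANK, nbins: int = DEFAULT_BINS) -> dict:
    """Coverage-weighted methylation meta-profile around TSSs.

    CpG betas within [tss-flank, tss+flank) are assigned to ``nbins``
    bins; minus-strand TSSs are mirrored so that bin 0 is always the
    most upstream position.  Bins with zero covered CpGs are NaN
    (missing, not zero).
    """
    meth_sum = np.zeros(nbins)
    cov_sum = np.zeros(nbins)
    bin_width = 2 * flank / nbins
    by_chrom = {c: sub for c, sub in calls.groupby("chrom", sort=False)}
    for site in tss.itertuples(index=False):
        sub = by_chrom.get(site.chrom)
        if sub is None:
            continue
        anchor = site.start if site.strand == "+" else site.end - 1
        lo, hi = anchor - flank, anchor + flank
        window = sub[(sub["pos"] >= lo) & (sub["pos"] < hi)]
        if window.empty:
            continue
        offsets = window["pos"].to_numpy() - lo
        bins = np.minimum((offsets / bin_width).astype(int), nbins - 1)
        if site.strand == "-":
            bins = nbins - 1 - bins
        cov = (window["meth"] + window["unmeth"]).to_numpy()
        np.add.at(meth_sum, bins, window["meth"].to_numpy())
        np.add.at(cov_sum, bins, cov)
    with np.errstate(invalid="ignore"):
        level = np.where(cov_sum > 0, meth_sum / np.where(cov_sum == 0, 1, cov_sum),
                         np.nan)
    centers = (np.arange(nbins) + 0.5) * bin_width - flank
    return {"bin_center": centers.tolist(),
            "level": [None if not np.isfinite(v) else float(v) for v in level],
            "coverage": cov_sum.tolist(),
            "flank": flank, "nbins": nbins, "n_tss": int(len(tss))}


# ---------------------------------------------------------------------------
# rendering

def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    svg = buf.getvalue()
    return svg[svg.index("<svg"):]


def _plot_composition(tables: dict, title: str) -> Optional[str]:
    if not tables:
        return None
    fig, axes = plt.subplots(1, max(len(tables), 1), figsize=(5 * len(tables), 3),
                             squeeze=False)
    for ax, (mate, table) in zip(axes[0], sorted(tables.items())):
        df = pd.DataFrame(table)
        if df.empty:
            ax.set_title(f"{title} ({mate}): no reads")
            continue
        for letter in "ACGTN":
            if letter in df:
                ax.plot(range(1, len(df) + 1), df[letter], label=letter, lw=1)
        ax.set_xlabel("cycle")
        ax.set_ylabel("fraction")
        ax.set_ylim(0, 1)
        ax.set_title(f"{title} ({mate})")
        ax.legend(fontsize=7, ncol=5)
    fig.tight_layout()
    return _fig_to_svg(fig)


def _plot_mbias(records) -> Optional[str]:
    if not records:
        return None
    df = pd.DataFrame(records, columns=["mate", "cycle", "meth", "unmeth", "level"])
    fig, ax = plt.subplots(figsize=(6, 3))
    for mate, sub in df.groupby("mate"):
        ax.plot(sub["cycle"], sub["level"], marker=".", lw=1, label=f"read {mate}")
    ax.set_xlabel("sequencing cycle")
    ax.set_ylabel("methylation level")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("M-bias")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return _fig_to_svg(fig)


def _plot_sizes(target: Optional[dict], spike: Optional[dict]) -> Optional[str]:
    if target is None:
        return None
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(target["lengths"], target["counts"], lw=1, label="DNA of interest")
    if spike and spike["lengths"]:
        ax.plot(spike["lengths"], spike["counts"], lw=1, label="spike-in")
    ax.set_xlabel("fragment size (bp)")
    ax.set_ylabel("fragments")
    ax.set_title("Fragment size distribution")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return _fig_to_svg(fig)


def _plot_per_chrom(levels: dict) -> Optional[str]:
    if not levels:
        return None
    fig, ax = plt.subplots(figsize=(max(3, 0.6 * len(levels) + 2), 3))
    names = list(levels)
    ax.bar(range(len(names)), [levels[n] for n in names], color="#4878a8")
    ax.set_xticks(range(len(names)), names, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("methylation level")
    ax.set_ylim(0, 1)
    ax.set_title("Per-chromosome methylation")
    fig.tight_layout()
    return _fig_to_svg(fig)


def _plot_tss(profile: Optional[dict]) -> Optional[str]:
    if not profile:
        return None
    x = profile["bin_center"]
    y = [np.nan if v is None else v for v in profile["level"]]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(x, y, lw=1.2, color="#a84848")
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("methylation level")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(f"TSS meta-profile (n={profile.get('n_tss', '?')})")
    fig.tight_layout()
    return _fig_to_svg(fig)


def _fmt(value, digits: int = 4) -> str:
    if value is None:
        return "n/a"
    if isinstance(value, float):
        return f"{value:.{digits}f}"
    return f"{value:,}" if isinstance(value, int) else str(value)


_SECTION_MISSING = '<p class="missing">not provided</p>'


def render_report(bundle: QCBundle, out_dir) -> Path:
    """Render ``report.html`` plus TSV sidecars into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_sidecars(bundle, out_dir)

    meta_rows = "".join(f"<tr><th>{k}</th><td>{_fmt(v)}</td></tr>"
                        for k, v in sorted(bundle.metadata.items()))
    trim = bundle.trim or {}
    aln = bundle.alignment or {}
    conv = bundle.conversion
    if conv and conv.get("estimable"):
        conv_html = (f"<p>Conversion rate (all contexts): <b>{conv['rate']:.4f}</b> "
                     f"({conv['converted_count']:,}/{conv['total_count']:,} "
                     f"cytosine observations on {conv['spike_in_name']}); "
                     f"CpG context: {_fmt(conv.get('cpg_rate'))}, "
                     f"non-CpG: {_fmt(conv.get('non_cpg_rate'))}.</p>")
    elif conv:
        conv_html = ('<p class="missing">not estimable: no informative '
                     'spike-in coverage</p>')
    else:
        conv_html = _SECTION_MISSING

    summary_rows = "".join(
        f"<tr><th>{label}</th><td>{_fmt(value)}</td></tr>" for label, value in [
            ("Input read pairs/reads", trim.get("total_pairs")),
            ("Kept after trimming", trim.get("kept_pairs")),
            ("Dropped too-short", trim.get("dropped_short")),
            ("Adapter-containing", trim.get("adapter_found")),
            ("Reads mapped", aln.get("n_mapped")),
            ("Low-quality alignments", aln.get("low_quality")),
            ("PCR duplicate fragments", aln.get("duplicates")),
            ("Reported fragments", aln.get("reported")),
            ("Overall methylation level", bundle.overall_level),
        ])

    sections = {
        "Base composition (before trimming)":
            _plot_composition(bundle.composition_before, "before"),
        "Base composition (after trimming)":
            _plot_composition(bundle.composition_after, "after"),
        "M-bias": _plot_mbias(bundle.m_bias),
        "Fragment sizes": _plot_sizes(bundle.size_hist_target, bundle.size_hist_spike)
            if bundle.size_note is None else f'<p class="missing">{bundle.size_note}</p>',
        "Per-chromosome methylation": _plot_per_chrom(bundle.per_chromosome),
        "TSS meta-profile": _plot_tss(bundle.tss_profile)
            if bundle.tss_note is None else f'<p class="missing">{bundle.tss_note}</p>',
    }
    body = "".join(
        f"<h2>{title}</h2>\n{content if content else _SECTION_MISSING}\n"
        for title, content in sections.items())

    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>metharc report</title>
<style>
body {{ font-family: sans-serif; max-width: 960px; margin: 2em auto; color: #222; }}
table {{ border-collapse: collapse; margin: 1em 0; }}
th, td {{ border: 1px solid #ccc; padding: 4px 10px; text-align: left; }}
th {{ background: #f0f0f0; }}
.missing {{ color: #999; font-style: italic; }}
</style></head><body>
<h1>metharc analysis report</h1>
<h2>Run metadata</h2>
<table>{meta_rows}</table>
<h2>Summary</h2>
<table>{summary_rows}</table>
<h2>Spike-in conversion rate</h2>
{conv_html}
{body}
</body></html>
"""
    out = out_dir / "report.html"
    out.write_text(html)
    return out


def _write_sidecars(bundle: QCBundle, out_dir: Path) -> None:
    if bundle.m_bias:
        pd.DataFrame(bundle.m_bias,
                     columns=["mate", "cycle", "meth", "unmeth", "level"]) \
            .to_csv(out_dir / "m_bias.tsv", sep="\t", index=False)
    if bundle.per_chromosome:
        pd.DataFrame(sorted(bundle.per_chromosome.items()),
                     columns=["chrom", "level"]) \
            .to_csv(out_dir / "per_chromosome.tsv", sep="\t", index=False)
    if bundle.size_hist_target:
        pd.DataFrame(bundle.size_hist_target) \
            .to_csv(out_dir / "size_target.tsv", sep="\t", index=False)
    if bundle.size_hist_spike:
        pd.DataFrame(bundle.size_hist_spike) \
            .to_csv(out_dir / "size_spikein.tsv", sep="\t", index=False)
    if bundle.tss_profile:
        pd.DataFrame({"bin_center": bundle.tss_profile["bin_center"],
                      "level": bundle.tss_profile["level"],
                      "coverage": bundle.tss_profile["coverage"]}) \
            .to_csv(out_dir / "tss_profile.tsv", sep="\t", index=False)
    for phase, tables in (("before", bundle.composition_before),
                          ("after", bundle.composition_after)):
        for mate, table in tables.items():
            pd.DataFrame(table).to_csv(
                out_dir / f"composition_{phase}_{mate}.tsv", sep="\t",
                index_label="row")
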