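"""Itemized block report (Items A–F) and cross-block comparison.

Item A: block metadata; Item B: the 20×20 pair-count matrix; Item C:
the derived-parameter summary; Item D: the residue-diversity table;
Item E: the hetero-pair probability table; Item F: the positional
summary with per-column profiles.  Everything is emitted as TSV with
fixed ordering and 1-decimal formatting, so identical inputs give
byte-identical output, and every percentage is re-derivable from the
Item B integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from scipy.stats import pearsonr

from .block import Block, RESIDUES
from .classes import ClassScheme
from .counting import PairCounts, count_pairs, write_counts_tsv
from .distribution import ProbabilityTable, probability_table
from .errors import InsufficientDataError, NoHeteroPairsError, ZeroVarianceError
from .parameters import BlockSummary, summarize
from .positional import PositionalSummary, positional_summary


def _fmt(x: float) -> str:
    return f"{x:.1f}"


@dataclass(frozen=True)
class BlockReport:
    """The full itemized analysis of one block."""

    name: str
    block: Block
    pair_counts: PairCounts           # Item B
    summary: BlockSummary             # Items C, D
    probability: ProbabilityTable | None  # Item E (None if no hetero-pairs)
    positional: PositionalSummary     # Item F


def build_report(
    block: Block, scheme: ClassScheme, name: str = "block"
) -> BlockReport:
    """Run every analysis module over one block."""
    pc = count_pairs(block)
    try:
        prob = probability_table(pc)
    except NoHeteroPairsError:
        prob = None
    return BlockReport(
        name=name,
        block=block,
        pair_counts=pc,
        summary=summarize(pc, scheme),
        probability=prob,
        positional=positional_summary(block, scheme),
    )


# ---------------------------------------------------------------- output

SUMMARY_COLUMNS = (
    "name", "width", "depth", "R", "E", "MDR", "MDR_RD", "RDmin",
    "RDmin_RD", "D", "D_pct", "CD_acidic", "CD_basic", "CD_non_polar",
    "CD_hydrophobic", "CD_hydrophilic", "no_hetero",
)


def summary_row(report: BlockReport) -> dict[str, str]:
    """Item C as one TSV row (family-table column order)."""
    s = report.summary
    row = {
        "name": report.name,
        "width": str(report.block.width),
        "depth": str(report.block.depth),
        "R": _fmt(s.R),
        "E": _fmt(s.E),
        "MDR": s.MDR or "-",
        "MDR_RD": _fmt(s.RD[s.MDR]) if s.MDR else "-",
        "RDmin": s.RDmin or "-",
        "RDmin_RD": _fmt(s.RD[s.RDmin]) if s.RDmin else "-",
        "D": s.D[0] if s.D else "-",
        "D_pct": _fmt(s.D[1]) if s.D else "-",
        "no_hetero": "1" if s.no_hetero else "0",
    }
    for cls in ("acidic", "basic", "non_polar", "hydrophobic", "hydrophilic"):
        row[f"CD_{cls}"] = _fmt(s.CD[cls]) if s.CD else "-"
    return row


def write_summary_tsv(reports: list[BlockReport], path: str | Path) -> None:
    lines = ["\t".join(SUMMARY_COLUMNS)]
    for rep in reports:
        row = summary_row(rep)
        lines.append("\t".join(row[c] for c in SUMMARY_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def read_summary_tsv(path: str | Path) -> list[dict[str, str]]:
    """Parse a summary TSV back into row dicts (round-trip partner)."""
    lines = Path(path).read_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:]]


def write_report(report: BlockReport, outdir: str | Path) -> None:
    """Write Items A–F as TSV files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    (out / "item_A_metadata.tsv").write_text(
        "name\twidth\tdepth\n"
        f"{report.name}\t{report.block.width}\t{report.block.depth}\n"
    )
    write_counts_tsv(report.pair_counts, out / "item_B_pair_counts.tsv")
    write_summary_tsv([report], out / "item_C_summary.tsv")

    rd_lines = ["residue\tRD"]
    for aa in RESIDUES:
        rd_lines.append(f"{aa}\t{_fmt(report.summary.RD[aa])}")
    (out / "item_D_residue_diversity.tsv").write_text(
        "\n".join(rd_lines) + "\n"
    )

    if report.probability is not None:
        e_lines = ["pair\tcount\tprobability"]
        for label, count, p in report.probability.entries:
            e_lines.append(f"{label}\t{count}\t{p:.6f}")
        (out / "item_E_probability.tsv").write_text("\n".join(e_lines) + "\n")
        b_lines = ["bin_lo\tbin_hi\tn_types\ttotal_count"]
        for b in report.probability.bins:
            b_lines.append(
                f"{b.lo:.6f}\t{b.hi:.6f}\t{b.n_types}\t{b.total_count}"
            )
        (out / "item_E_probability_bins.tsv").write_text(
            "\n".join(b_lines) + "\n"
        )
    else:
        (out / "item_E_probability.tsv").write_text(
            "pair\tcount\tprobability\n# no hetero-pairs observed\n"
        )

    f_lines = ["column\tentropy_bits\tconserved\tcategory"]
    for p in report.positional.profiles:
        f_lines.append(
            f"{p.column_index + 1}\t{p.entropy_bits:.4f}"
            f"\t{int(p.conserved)}\t{p.category}"
        )
    (out / "item_F_columns.tsv").write_text("\n".join(f_lines) + "\n")

    agg = report.positional
    g_cols = ["name", "INV", "CONV"] + [
        c for c in agg.category_percent if c != "INV"
    ]
    g_vals = [report.name, _fmt(agg.percent_invariant),
              _fmt(agg.percent_conserved)] + [
        _fmt(agg.category_percent[c])
        for c in agg.category_percent if c != "INV"
    ]
    (out / "item_F_summary.tsv").write_text(
        "\t".join(g_cols) + "\n" + "\t".join(g_vals) + "\n"
    )


# ------------------------------------------------------------- comparison

def correlate_with_divergence(
    pairs: list[tuple[BlockSummary | float, float]],
) -> float:
    """Pearson r between R and divergence rate across blocks.

    ``pairs`` holds (summary-or-R-value, divergence rate) tuples; rates
    are literature values supplied by the user.  Needs at least three
    blocks and non-degenerate variances.
    """
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"need >= 3 blocks with rates, got {len(pairs)}"
        )
    rs = [
        s.R if isinstance(s, BlockSummary) else float(s) for s, _ in pairs
    ]
    rates = [float(rate) for _, rate in pairs]
    if len(set(rs)) == 1 or len(set(rates)) == 1:
        raise ZeroVarianceError("R or rate column has zero variance")
    return float(pearsonr(rs, rates).statistic)


def read_rates_tsv(path: str | Path) -> dict[str, float]:
    """Two-column (block name, rate) TSV of literature divergence rates."""
    rates: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        name, value = line.split("\t")
        rates[name.strip()] = float(value)
    return rates
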