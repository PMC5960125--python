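"""Readers and writers for the tool's external file formats.

Formats:

* segments TSV — header ``sample chromosome start end state``; 1-based
  inclusive coordinates; state case-insensitive among gain/loss/loh.
* groups TSV — header ``sample group``; exactly two distinct group labels.
* gene annotation — BED4+ (0-based half-open); converted to 1-based
  inclusive on read.
* gene sets — standard GMT (name, description, member genes).
* results TSV — one row per reported region, sorted by q-value (ties by
  p-value, then coordinates); frequencies printed as percentages with one
  decimal, ranges as ``lo-hi`` for merged regions.
"""

from __future__ import annotations

from typing import IO, Iterable

from .association import RegionResult
from .types import CNVCall, GeneRecord, GeneSetCollection, normalize_state


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _rows(stream: IO[str]):
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        yield lineno, line.split("\t")


def read_segments(stream: IO[str]) -> list[CNVCall]:
    """Read a segments TSV into CNV calls."""
    rows = _rows(stream)
    try:
        lineno, header = next(rows)
    except StopIteration:
        raise ParseError("empty segments file (header required)") from None
    if [h.strip().lower() for h in header] != ["sample", "chromosome", "start", "end", "state"]:
        raise ParseError(f"line {lineno}: bad header {header!r}")
    calls = []
    for lineno, fields in rows:
        if len(fields) != 5:
            raise ParseError(f"line {lineno}: expected 5 columns, got {len(fields)}")
        sample, chrom, start_s, end_s, state_s = (f.strip() for f in fields)
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer coordinate") from None
        try:
            call = CNVCall(sample, chrom, start, end, normalize_state(state_s))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        calls.append(call)
    return calls


def write_segments(calls: Iterable[CNVCall], stream: IO[str]) -> None:
    stream.write("sample\tchromosome\tstart\tend\tstate\n")
    for c in calls:
        stream.write(f"{c.sample_id}\t{c.chromosome}\t{c.start}\t{c.end}\t{c.state}\n")


def read_groups(
    stream: IO[str], group1_label: str | None = None
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Read the sample-to-group TSV.

    Group 1 is the label of first appearance unless ``group1_label`` pins
    it. Exactly two distinct labels must be present and no sample may be
    listed twice.
    """
    rows = _rows(stream)
    try:
        lineno, header = next(rows)
    except StopIteration:
        raise ParseError("empty groups file (header required)") from None
    if [h.strip().lower() for h in header] != ["sample", "group"]:
        raise ParseError(f"line {lineno}: bad header {header!r}")
    order: list[str] = []
    members: dict[str, list[str]] = {}
    seen: set[str] = set()
    for lineno, fields in rows:
        if len(fields) != 2:
            raise ParseError(f"line {lineno}: expected 2 columns, got {len(fields)}")
        sample, label = (f.strip() for f in fields)
        if sample in seen:
            raise ParseError(f"line {lineno}: sample {sample!r} listed twice")
        seen.add(sample)
        if label not in members:
            members[label] = []
            order.append(label)
        members[label].append(sample)
    if len(order) != 2:
        raise ParseError(f"expected exactly 2 group labels, found {len(order)}: {order}")
    if group1_label is not None:
        if group1_label not in members:
            raise ParseError(f"group label {group1_label!r} not present in groups file")
        first = group1_label
    else:
        first = order[0]
    second = order[1] if order[0] == first else order[0]
    return tuple(members[first]), tuple(members[second])


def write_groups(
    group1: Iterable[str], group2: Iterable[str], stream: IO[str],
    labels: tuple[str, str] = ("group1", "group2"),
) -> None:
    stream.write("sample\tgroup\n")
    for s in group1:
        stream.write(f"{s}\t{labels[0]}\n")
    for s in group2:
        stream.write(f"{s}\t{labels[1]}\n")


def read_gene_annotation(stream: IO[str]) -> list[GeneRecord]:
    """Read BED4+ gene records, converting to 1-based inclusive coordinates."""
    genes = []
    for lineno, fields in _rows(stream):
        if fields[0].startswith(("#", "track", "browser")):
            continue
        if len(fields) < 4:
            raise ParseError(f"line {lineno}: BED needs >= 4 columns (4th = gene id)")
        chrom, start_s, end_s, name = (f.strip() for f in fields[:4])
        try:
            bed_start, bed_end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer coordinate") from None
        if bed_end <= bed_start:
            raise ParseError(f"line {lineno}: BED end must exceed start")
        genes.append(GeneRecord(name, chrom, bed_start + 1, bed_end))
    return genes


def read_gmt(stream: IO[str]) -> GeneSetCollection:
    """Read GMT gene sets; duplicate genes within a line are collapsed."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, fields in _rows(stream):
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: GMT needs name, description and >= 1 gene")
        name = fields[0].strip()
        if name in sets:
            raise ParseError(f"line {lineno}: duplicate gene set name {name!r}")
        genes = frozenset(g.strip() for g in fields[2:] if g.strip())
        if not genes:
            raise ParseError(f"line {lineno}: gene set {name!r} has no genes")
        sets[name] = genes
    return GeneSetCollection(sets)


def format_frequency(interval: tuple[float, float]) -> str:
    """Render a frequency interval as percentage text, e.g. 21.4 or 23-31."""
    def one(x: float) -> str:
        text = f"{x * 100:.1f}"
        return text[:-2] if text.endswith(".0") else text

    lo, hi = interval
    return one(lo) if one(lo) == one(hi) else f"{one(lo)}-{one(hi)}"


def _result_sort_key(r: RegionResult):
    q = r.q_value if r.q_value is not None else float("inf")
    p = r.p_value if r.p_value is not None else float("inf")
    return (q, p, r.chromosome, r.start, r.end)


def write_region_results(
    results: list[RegionResult], stream: IO[str], model: str | None = None
) -> None:
    """Write the results TSV, sorted by q-value (then p, then coordinates).

    Statistical rows carry the event type, its p-value and the event type's
    per-group frequency; query rows are typeless and report per-group
    frequencies of all three variant states.
    """
    if model is None:
        model = results[0].model if results else "statistical"
    if model == "statistical":
        stream.write(
            "chromosome\tstart\tend\ttype\tp_value\tq_value\tgroup1_freq\tgroup2_freq\n"
        )
    else:
        stream.write(
            "chromosome\tstart\tend\tq_value\t"
            "group1_gain\tgroup1_loss\tgroup1_loh\t"
            "group2_gain\tgroup2_loss\tgroup2_loh\n"
        )
    for r in sorted(results, key=_result_sort_key):
        q = "" if r.q_value is None else f"{r.q_value:.6g}"
        if model == "statistical":
            stream.write(
                f"{r.chromosome}\t{r.start}\t{r.end}\t{r.event_type}\t"
                f"{r.p_value:.6g}\t{q}\t"
                f"{format_frequency(r.group1_freq[r.event_type])}\t"
                f"{format_frequency(r.group2_freq[r.event_type])}\n"
            )
        else:
            cells = [format_frequency(r.group1_freq[s]) for s in ("Gain", "Loss", "LOH")]
            cells += [format_frequency(r.group2_freq[s]) for s in ("Gain", "Loss", "LOH")]
            stream.write(
                f"{r.chromosome}\t{r.start}\t{r.end}\t{q}\t" + "\t".join(cells) + "\n"
            )


def read_result_regions(stream: IO[str]) -> list[tuple[str, int, int]]:
    """Read (chromosome, start, end) back from a results TSV."""
    rows = _rows(stream)
    try:
        lineno, header = next(rows)
    except StopIteration:
        raise ParseError("empty results file") from None
    cols = [h.strip().lower() for h in header]
    if cols[:3] != ["chromosome", "start", "end"]:
        raise ParseError(f"line {lineno}: results header must start chromosome/start/end")
    regions = []
    for lineno, fields in rows:
        try:
            regions.append((fields[0], int(fields[1]), int(fields[2])))
        except (IndexError, ValueError):
            raise ParseError(f"line {lineno}: bad region row") from None
    return regions


def write_enrichment_results(results, stream: IO[str]) -> None:
    stream.write("set_name\tk\tK\tn\tN\tp_value\tp_adjusted\tq_value\tgenes\n")
    for r in results:
        genes = ";".join(sorted(r.overlap_genes))
        stream.write(
            f"{r.set_name}\t{r.overlap_k}\t{r.set_size_K}\t{r.query_size_n}\t"
            f"{r.universe_N}\t{r.p_value:.6g}\t{r.p_adjusted:.6g}\t{r.q_value:.6g}\t{genes}\n"
        )
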