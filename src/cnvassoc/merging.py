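"""Merging of reported regions in close proximity.

Segmentation can leave several reported regions in a row with very similar
carrier distributions, or a caller may split one event by a few bases. Two
reported results on the same chromosome are mergeable when the gap between
them (next.start - current.end - 1, so directly adjacent regions have gap 0)
is at most the distance threshold and, for the statistical model, they carry
the same event type; query-model results are typeless and merge freely.
Merging chains transitively; the merged span includes the gaps, the merged
p-value is the largest (least significant) constituent p-value, and each
group/state frequency becomes the [min, max] interval over constituents.

Merged results no longer satisfy the "no sample changes state" region
invariant; they are flagged with ``merged=True``.
"""

from __future__ import annotations

from collections import defaultdict

from .association import RegionResult


def _merge_chain(chain: list[RegionResult]) -> RegionResult:
    if len(chain) == 1:
        return chain[0]
    first = chain[0]
    g1 = {
        state: (min(r.group1_freq[state][0] for r in chain),
                max(r.group1_freq[state][1] for r in chain))
        for state in first.group1_freq
    }
    g2 = {
        state: (min(r.group2_freq[state][0] for r in chain),
                max(r.group2_freq[state][1] for r in chain))
        for state in first.group2_freq
    }
    p = None
    if first.model == "statistical":
        p = max(r.p_value for r in chain)
    return RegionResult(
        chromosome=first.chromosome,
        start=min(r.start for r in chain),
        end=max(r.end for r in chain),
        model=first.model,
        event_type=first.event_type,
        p_value=p,
        group1_freq=g1,
        group2_freq=g2,
        merged=True,
    )


def merge_adjacent_results(
    results: list[RegionResult],
    distance_threshold_bp: int,
    model: str,
) -> list[RegionResult]:
    """Greedy left-to-right chain merge of nearby same-type results.

    ``model`` selects the type rule: 'statistical' merges only results of
    the same event type; 'query' merges any nearby results. The scan is
    greedy but order-independent, since mergeability depends only on
    pairwise gaps (and type).
    """
    if distance_threshold_bp < 0:
        raise ValueError("distance threshold must be >= 0")
    if model not in ("statistical", "query"):
        raise ValueError(f"unknown model {model!r}")
    if not results:
        return []

    # partition into independent merge lanes
    lanes: dict[tuple, list[RegionResult]] = defaultdict(list)
    for r in results:
        key = (r.chromosome, r.event_type) if model == "statistical" else (r.chromosome,)
        lanes[key].append(r)

    merged: list[RegionResult] = []
    for lane in lanes.values():
        lane.sort(key=lambda r: (r.start, r.end))
        chain = [lane[0]]
        span_end = lane[0].end
        for r in lane[1:]:
            gap = r.start - span_end - 1
            if gap <= distance_threshold_bp:
                chain.append(r)
                span_end = max(span_end, r.end)
            else:
                merged.append(_merge_chain(chain))
                chain = [r]
                span_end = r.end
        merged.append(_merge_chain(chain))
    merged.sort(key=lambda r: (r.chromosome, r.start, r.end, r.event_type or ""))
    return merged
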