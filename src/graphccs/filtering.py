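"""Multidimensional candidate filtering: m/z, then retention time, then CCS.

A query (an observed feature with m/z and optionally RT and CCS) is
matched against a compound library.  Filtering is staged: the m/z window
yields the MList, the RT window narrows it to the RList, and the CCS
window narrows that to the CList, whose members are ranked by a fused
score combining the normalized per-dimension errors.  recall@k measures
how often the true compound lands in the top k of the final ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import EmptyLibraryError, MissingTruthError


@dataclass(frozen=True)
class LibraryEntry:
    identifier: str
    smiles: str
    adduct: str
    mz: float                  # Da
    rt: float | None = None    # predicted minutes
    ccs: float | None = None   # predicted Å²

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"{self.identifier}: mz must be positive")


@dataclass(frozen=True)
class Query:
    mz: float
    rt: float | None = None
    ccs: float | None = None
    true_identifier: str | None = None


@dataclass(frozen=True)
class Thresholds:
    mz_ppm: float = 10.0        # m/z window, parts per million
    rt_tolerance: float = 1.0   # absolute minutes
    ccs_percent: float = 3.0    # CCS window, percent of observed value


@dataclass
class CandidateMatch:
    entry: LibraryEntry
    mz_error_ppm: float
    rt_error: float | None
    ccs_error_percent: float | None
    fused_score: float = 0.0


def _fused_score(match: CandidateMatch, thresholds: Thresholds,
                 weights: tuple[float, float, float]) -> float:
    """1 minus the weighted mean of threshold-normalized errors.

    Dimensions absent from the query are excluded and the weights
    renormalized, so the score is monotone non-increasing in every
    available error dimension.
    """
    terms = [(weights[0], abs(match.mz_error_ppm) / thresholds.mz_ppm)]
    if match.rt_error is not None:
        terms.append((weights[1], abs(match.rt_error) / thresholds.rt_tolerance))
    if match.ccs_error_percent is not None:
        terms.append((weights[2],
                      abs(match.ccs_error_percent) / thresholds.ccs_percent))
    total_w = sum(w for w, _ in terms)
    return 1.0 - sum(w * e for w, e in terms) / total_w


def filter_candidates(query: Query, library: list[LibraryEntry],
                      thresholds: Thresholds | None = None,
                      weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                      use_rt: bool = True, use_ccs: bool = True,
                      ) -> tuple[list[CandidateMatch], dict]:
    """Staged m/z -> RT -> CCS filtering with fused-score ranking.

    Returns the ranked CList and the stage counts {mlist, rlist, clist}.
    A stage is skipped (passes everything through) when the query or the
    stage flag lacks that dimension, so |MList| >= |RList| >= |CList|
    always holds.  Ties break on smaller m/z error, then identifier.
    """
    if not library:
        raise EmptyLibraryError("cannot filter against an empty library")
    thresholds = thresholds or Thresholds()

    mlist: list[CandidateMatch] = []
    for entry in library:
        ppm = (entry.mz - query.mz) / query.mz * 1e6
        if abs(ppm) <= thresholds.mz_ppm:
            mlist.append(CandidateMatch(entry, ppm, None, None))

    rlist: list[CandidateMatch] = []
    for match in mlist:
        if use_rt and query.rt is not None and match.entry.rt is not None:
            rt_err = match.entry.rt - query.rt
            if abs(rt_err) > thresholds.rt_tolerance:
                continue
            match.rt_error = rt_err
        rlist.append(match)

    clist: list[CandidateMatch] = []
    for match in rlist:
        if use_ccs and query.ccs is not None and match.entry.ccs is not None:
            ccs_err = (match.entry.ccs - query.ccs) / query.ccs * 100.0
            if abs(ccs_err) > thresholds.ccs_percent:
                continue
            match.ccs_error_percent = ccs_err
        clist.append(match)

    for match in clist:
        match.fused_score = _fused_score(match, thresholds, weights)
    clist.sort(key=lambda m: (-m.fused_score, abs(m.mz_error_ppm),
                              m.entry.identifier))
    counts = {"mlist": len(mlist), "rlist": len(rlist), "clist": len(clist)}
    return clist, counts


def recall_at_k(queries: list[Query], library: list[LibraryEntry],
                thresholds: Thresholds | None = None, k: int = 1,
                weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                use_rt: bool = True, use_ccs: bool = True) -> float:
    """Percentage of queries whose true compound ranks within the top k."""
    if not queries:
        raise MissingTruthError("no queries")
    hits = 0
    for query in queries:
        if query.true_identifier is None:
            raise MissingTruthError("query lacks its true identifier")
        ranked, _ = filter_candidates(query, library, thresholds,
                                      weights, use_rt, use_ccs)
        top = [m.entry.identifier for m in ranked[:k]]
        if query.true_identifier in top:
            hits += 1
    return 100.0 * hits / len(queries)
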