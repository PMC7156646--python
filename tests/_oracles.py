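"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately written naively (pairwise loops over
exon chains, explicit set algebra) so that agreement with the package's
optimized implementations is a meaningful check.
"""

import itertools

import numpy as np


def _junc(chain):
    return {(chain[i][1], chain[i + 1][0]) for i in range(len(chain) - 1)}


def _overlap(a, b):
    return a[0] < b[1] and b[0] < a[1]


def oracle_events(gene):
    """Enumerate (etype, inclusion, total, region) tuples by brute force.

    ``gene`` is a GeneModel; coordinates are genomic 0-based half-open.
    Returns a set of canonical event keys comparable with the package
    detectors (ORF-overlap filtering not applied).
    """
    chains = {i.transcript_id: list(i.exons) for i in gene.isoforms}
    junc = {t: _junc(c) for t, c in chains.items()}
    exons_of = {t: set(map(tuple, c)) for t, c in chains.items()}
    strand = gene.strand
    out = set()

    def key(etype, incl, total, region):
        return (etype, frozenset(incl), frozenset(total), tuple(region))

    # SE -----------------------------------------------------------------
    seen = set()
    for t, chain in chains.items():
        for i in range(1, len(chain) - 1):
            s2, e2 = chain[i]
            e1, s3 = chain[i - 1][1], chain[i + 1][0]
            if (e1, s2, e2, s3) in seen:
                continue
            seen.add((e1, s2, e2, s3))
            excl = {u for u in chains if (e1, s3) in junc[u]}
            incl = {
                u for u in chains
                if (e1, s2) in junc[u] and (e2, s3) in junc[u]
            }
            if incl and excl and (incl | excl) - incl:
                out.add(key("SE", incl, incl | excl, (s2, e2)))

    # A3 / A5 ------------------------------------------------------------
    all_j = set().union(*junc.values()) if junc else set()
    donors = {}
    acceptors = {}
    for d, a in all_j:
        donors.setdefault(d, set()).add(a)
        acceptors.setdefault(a, set()).add(d)

    def exon_with_start(a, txs):
        for t in txs:
            for ex in chains[t]:
                if ex[0] == a:
                    return ex
        return None

    def exon_with_end(d, txs):
        for t in txs:
            for ex in chains[t]:
                if ex[1] == d:
                    return ex
        return None

    for d, accs in donors.items():
        for a1, a2 in itertools.combinations(sorted(accs), 2):
            incl = {t for t in chains if (d, a1) in junc[t]}
            excl = {t for t in chains if (d, a2) in junc[t]}
            ex1 = exon_with_start(a1, incl)
            ex2 = exon_with_start(a2, excl)
            if not ex1 or not ex2 or not _overlap(ex1, ex2):
                continue
            if not incl or not excl or not (incl | excl) - incl:
                continue
            etype = "A3" if strand == "+" else "A5"
            out.add(key(etype, incl, incl | excl, (a1, a2)))

    for a, dons in acceptors.items():
        for d1, d2 in itertools.combinations(sorted(dons), 2):
            incl = {t for t in chains if (d2, a) in junc[t]}
            excl = {t for t in chains if (d1, a) in junc[t]}
            ex1 = exon_with_end(d1, excl)
            ex2 = exon_with_end(d2, incl)
            if not ex1 or not ex2 or not _overlap(ex1, ex2):
                continue
            if not incl or not excl or not (incl | excl) - incl:
                continue
            etype = "A5" if strand == "+" else "A3"
            out.add(key(etype, incl, incl | excl, (d1, d2)))

    # MX -----------------------------------------------------------------
    internal = {}
    for t, chain in chains.items():
        for i in range(1, len(chain) - 1):
            e1, s4 = chain[i - 1][1], chain[i + 1][0]
            internal.setdefault((e1, s4), set()).add(chain[i])
    for (e1, s4), exset in internal.items():
        for exA, exB in itertools.combinations(sorted(exset), 2):
            if _overlap(exA, exB):
                continue
            inclA = {
                t for t in chains
                if (e1, exA[0]) in junc[t] and (exA[1], s4) in junc[t]
            }
            inclB = {
                t for t in chains
                if (e1, exB[0]) in junc[t] and (exB[1], s4) in junc[t]
            }
            if not inclA or not inclB or (inclA & inclB):
                continue
            if any(exA in exons_of[t] and exB in exons_of[t] for t in chains):
                continue
            out.add(key("MX", inclA, inclA | inclB, (exA[0], exB[1])))

    # RI -----------------------------------------------------------------
    seen = set()
    for t, chain in chains.items():
        for (s_up, e_up), (s_dn, e_dn) in zip(chain, chain[1:]):
            if (s_up, e_up, s_dn, e_dn) in seen:
                continue
            seen.add((s_up, e_up, s_dn, e_dn))
            incl = {u for u in chains if (s_up, e_dn) in exons_of[u]}
            excl = {
                u for u in chains
                if (e_up, s_dn) in junc[u]
                and (s_up, e_up) in exons_of[u]
                and (s_dn, e_dn) in exons_of[u]
            }
            if incl and excl and (incl | excl) - incl:
                out.add(key("RI", incl, incl | excl, (e_up, s_dn)))

    # AF / AL ------------------------------------------------------------
    multi = {t: c for t, c in chains.items() if len(c) >= 2}
    for which in ("first", "last"):
        edge = {t: (c[0] if which == "first" else c[-1]) for t, c in multi.items()}
        nxt = {
            t: (multi[t][1][0] if which == "first" else multi[t][-2][1])
            for t in multi
        }
        for exA, exB in itertools.combinations(sorted(set(edge.values())), 2):
            if _overlap(exA, exB):
                continue
            txA = {t for t, e in edge.items() if e == exA}
            txB = {t for t, e in edge.items() if e == exB}
            for x in {nxt[a] for a in txA} & {nxt[b] for b in txB}:
                inclA = {t for t in txA if nxt[t] == x}
                inclB = {t for t in txB if nxt[t] == x}
                if not inclA or not inclB:
                    continue
                if which == "first":
                    etype = "AF" if strand == "+" else "AL"
                else:
                    etype = "AL" if strand == "+" else "AF"
                out.add(key(etype, inclA, inclA | inclB, (exA[0], exB[1])))

    return out


def event_keys(events):
    """Canonical keys for package SplicingEvent objects."""
    return {
        (e.etype, frozenset(e.inclusion), frozenset(e.total), tuple(e.region))
        for e in events
    }


# ---------------------------------------------------------------------------
# Stable matching


def gale_shapley(scores, min_score=0.8):
    """Textbook deferred-acceptance stable matching (A proposes).

    ``scores`` is a list of objects with id_a, id_b and a ``score``
    property. With strict, symmetric preferences the stable matching is
    unique, so this is a valid oracle for any stable-matching algorithm.
    """
    pref = {}
    rank_b = {}
    score_of = {}
    for s in scores:
        if s.score < min_score:
            continue
        pref.setdefault(s.id_a, []).append((-s.score, s.id_b))
        rank_b.setdefault(s.id_b, {})[s.id_a] = s.score
        score_of[(s.id_a, s.id_b)] = s.score
    for a in pref:
        pref[a].sort()
    queue = list(pref)
    nxt = {a: 0 for a in pref}
    engaged_b = {}
    engaged_a = {}
    while queue:
        a = queue.pop()
        while nxt[a] < len(pref[a]):
            _, b = pref[a][nxt[a]]
            nxt[a] += 1
            cur = engaged_b.get(b)
            if cur is None:
                engaged_b[b] = a
                engaged_a[a] = b
                break
            if rank_b[b][a] > rank_b[b][cur]:
                engaged_b[b] = a
                engaged_a[a] = b
                del engaged_a[cur]
                queue.append(cur)
                break
    return sorted((a, b, score_of[(a, b)]) for a, b in engaged_a.items())


def exhaustive_stable_matchings(scores, min_score=0.8):
    """All stable matchings by exhaustive enumeration (tiny instances only)."""
    cand = [s for s in scores if s.score >= min_score]
    ids_a = sorted({s.id_a for s in cand})
    by_pair = {(s.id_a, s.id_b): s.score for s in cand}

    def all_matchings(i, used_b, acc):
        if i == len(ids_a):
            yield list(acc)
            return
        a = ids_a[i]
        yield from all_matchings(i + 1, used_b, acc)  # a unmatched
        for (pa, pb), sc in by_pair.items():
            if pa == a and pb not in used_b:
                acc.append((pa, pb, sc))
                yield from all_matchings(i + 1, used_b | {pb}, acc)
                acc.pop()

    def stable(matching):
        sa = {a: s for a, _, s in matching}
        sb = {b: s for _, b, s in matching}
        pairs = {(a, b) for a, b, _ in matching}
        for (a, b), sc in by_pair.items():
            if (a, b) in pairs:
                continue
            if sc > sa.get(a, -1.0) and sc > sb.get(b, -1.0):
                return False
        return True

    return [sorted(m) for m in all_matchings(0, set(), []) if stable(m)]


# ---------------------------------------------------------------------------
# Peptide matching


def naive_peptide_match(peptides, proteome, max_mismatch=2, min_pep_len=7):
    """Reference implementation with plain Python string loops."""
    results = {}
    for pep in peptides:
        if len(pep) < min_pep_len:
            continue
        exact, near = set(), set()
        for orf, seq in proteome.items():
            k = len(pep)
            best = None
            for i in range(len(seq) - k + 1):
                mm = sum(1 for x, y in zip(pep, seq[i:i + k]) if x != y)
                best = mm if best is None else min(best, mm)
            if best is None:
                continue
            if best == 0:
                exact.add(orf)
            if best <= max_mismatch:
                near.add(orf)
        kept = len(exact) == 1 and not (near - exact)
        results[pep] = (exact, near, kept)
    return results
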