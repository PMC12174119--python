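"""Independent brute-force oracles used only by the test suite.

Every function here recomputes a quantity by the most literal possible
method — plain Python loops over raw events, exhaustive enumeration,
pairwise counting — deliberately sharing no code with the package
implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations


def oracle_biomarkers(events, min_pause_ms: int = 50) -> dict:
    """Event-scan recomputation of the 20 kinematic biomarkers (everything
    except the task score, whose rubric is algorithmic rather than a
    closed-form functional of the stream).

    ``events`` is an iterable of ``(t_ms, x, y, phase)`` tuples.
    """
    strokes: list[list[tuple]] = []
    cur = None
    for t, x, y, p in events:
        if p == "down":
            cur = [(t / 1000.0, x, y)]
        elif p == "move":
            cur.append((t / 1000.0, x, y))
        else:  # up
            cur.append((t / 1000.0, x, y))
            strokes.append(cur)
            cur = None
    assert cur is None, "dangling stroke in oracle input"
    J = len(strokes)
    assert J >= 1

    durations = [s[-1][0] - s[0][0] for s in strokes]
    lengths = []
    for s in strokes:
        d = 0.0
        for (t0, x0, y0), (t1, x1, y1) in zip(s, s[1:]):
            d += math.hypot(x1 - x0, y1 - y0)
        lengths.append(d)
    speeds = [(d / t if t > 0 else 0.0)
              for d, t in zip(lengths, durations) if not (t <= 0 and d > 0)]
    gaps = [strokes[j + 1][0][0] - strokes[j][-1][0] for j in range(J - 1)]

    initial = strokes[0][0][0]
    total = strokes[-1][-1][0]
    writing = sum(durations)
    process_pause = sum(gaps)

    def pop_sd(vals):
        m = sum(vals) / len(vals)
        return math.sqrt(sum((v - m) ** 2 for v in vals) / len(vals))

    # within-stroke stationary episodes
    pauses = 0
    for s in strokes:
        if min_pause_ms == 0:
            pauses += sum(1 for a, b in zip(s, s[1:])
                          if a[1] == b[1] and a[2] == b[2])
            continue
        k = 0
        while k < len(s) - 1:
            if s[k][1] == s[k + 1][1] and s[k][2] == s[k + 1][2]:
                j = k
                while j < len(s) - 1 and s[j][1] == s[j + 1][1] \
                        and s[j][2] == s[j + 1][2]:
                    j += 1
                if (s[j][0] - s[k][0]) * 1000.0 >= min_pause_ms - 1e-6:
                    pauses += 1
                k = j
            else:
                k += 1

    out = {
        "IPSDB_1": total,
        "IPSDB_2": total - initial,
        "IPSDB_3": writing,
        "IPSDB_4": initial + process_pause,
        "IPSDB_5": initial,
        "IPSDB_6": process_pause,
        "IPSDB_10": float(pauses),
        "EFDB_2": float(J),
        "EFDB_3": J / total * 60.0,
        "EFDB_4": writing / total,
        "EFDB_5": sum(lengths),
        "EFDB_6": max(lengths),
        "EFDB_7": sum(lengths) / J,
        "EFDB_8": pop_sd(lengths) / (sum(lengths) / J),
    }
    if gaps:
        mean_gap = process_pause / len(gaps)
        out["IPSDB_7"] = max(gaps)
        out["IPSDB_8"] = mean_gap
        out["IPSDB_9"] = pop_sd(gaps) / mean_gap if mean_gap > 0 else 0.0
    else:
        out["IPSDB_7"] = out["IPSDB_8"] = out["IPSDB_9"] = math.nan
    if speeds:
        mean_v = sum(speeds) / len(speeds)
        out["EFDB_9"] = max(speeds)
        out["EFDB_10"] = mean_v
        out["EFDB_11"] = pop_sd(speeds) / mean_v if mean_v > 0 else 0.0
    return out


def oracle_auc(pos, neg) -> float:
    """AUC as literal pairwise concordance: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def oracle_mannwhitney_p(x, y) -> float:
    """Exhaustive-permutation two-sided Mann–Whitney p (tie-aware)."""
    pooled = list(x) + list(y)
    n, nx = len(pooled), len(x)
    mu = nx * (n - nx) / 2.0

    def u_of(idx):
        a = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(n) if i not in set(idx)]
        return sum((1.0 if p > q else 0.5 if p == q else 0.0)
                   for p in a for q in rest)

    dev = abs(u_of(tuple(range(nx))) - mu) - 1e-12
    assigns = list(combinations(range(n), nx))
    hits = sum(1 for idx in assigns if abs(u_of(idx) - mu) >= dev)
    return hits / len(assigns)


def oracle_segment(events):
    """Brute-force segmentation: pair each down with the next up.

    Returns (n_strokes, initial_pause_s, gaps_s, total_s).
    """
    downs = [t for t, _, _, p in events if p == "down"]
    ups = [t for t, _, _, p in events if p == "up"]
    assert len(downs) == len(ups)
    gaps = [(d - u) / 1000.0 for d, u in zip(downs[1:], ups[:-1])]
    return len(downs), downs[0] / 1000.0, gaps, ups[-1] / 1000.0
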