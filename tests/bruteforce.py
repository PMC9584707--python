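"""Independent brute-force reference for the entropy estimator.

Pure-Python, explicit double loops over all vector pairs, no numpy
vectorization — deliberately naive so it shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import math


def bruteforce_entropy(
    data: list[list[float]],
    m: int,
    tau: int,
    r_coeff: float,
    n: float,
    B: int,
    s: int,
    baseline: bool = True,
    metric: str = "chebyshev",
) -> float:
    c = len(data)
    N = len(data[0])

    # coarse-grain: non-overlapping window means, remainder discarded
    n_s = N // s
    cg = [[sum(ch[j * s : (j + 1) * s]) / s for j in range(n_s)] for ch in data]

    # pooled population SD of the coarse-grained matrix
    flat = [v for ch in cg for v in ch]
    mean = sum(flat) / len(flat)
    sd = math.sqrt(sum((v - mean) ** 2 for v in flat) / len(flat))
    r = r_coeff * sd

    # composite delay vectors, optional per-block baseline removal
    V = n_s - (m - 1) * tau
    vecs = []
    for j in range(V):
        vec: list[float] = []
        for ch in range(c):
            block = [cg[ch][j + k * tau] for k in range(m)]
            if baseline:
                bm = sum(block) / m
                block = [x - bm for x in block]
            vec.extend(block)
        vecs.append(vec)

    # all distinct pairs, fuzzy similarity
    mus = []
    for i in range(V):
        for j in range(i + 1, V):
            if metric == "chebyshev":
                d = max(abs(a - b) for a, b in zip(vecs[i], vecs[j]))
            else:
                d = math.sqrt(sum((a - b) ** 2 for a, b in zip(vecs[i], vecs[j])))
            mus.append(math.exp(-((d / r) ** n)))

    # histogram over [0, 1]: interior edges upward, 1.0 in the last bin
    counts = [0] * B
    for v in mus:
        for k in range(B):
            if (k / B <= v < (k + 1) / B) or (k == B - 1 and v >= k / B):
                counts[k] += 1
                break

    total = len(mus)
    ent = 0.0
    for cnt in counts:
        if cnt:
            p = cnt / total
            ent -= p * math.log2(p)
    return ent / math.log2(B)
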