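"""Independent brute-force implementations of every descriptor.

Pure-Python loop/sum evaluations, deliberately written without the
package's vectorised code paths, used as oracles in the unit and
acceptance tests.
"""

import math


def com(coords, masses):
    total = sum(masses)
    return [
        sum(m * c[k] for m, c in zip(masses, coords)) / total for k in range(3)
    ]


def dist(a, b):
    return math.sqrt(sum((a[k] - b[k]) ** 2 for k in range(3)))


def _nxt(i, off, n):
    return (i - 1 + off) % n + 1


def d1(conf, topo):
    n = topo.n_units
    c = conf.coords.tolist()
    return [
        dist(c[topo.role_index(i, "O2")], c[topo.role_index(_nxt(i, 1, n), "O3")])
        for i in range(1, n + 1)
    ]


def d2(conf, topo):
    n = topo.n_units
    c = conf.coords.tolist()
    return [
        dist(c[topo.role_index(i, "O4")], c[topo.role_index(_nxt(i, 1, n), "O4")])
        for i in range(1, n + 1)
    ]


def d3(conf, topo):
    n = topo.n_units
    c = conf.coords.tolist()
    m = topo.masses.tolist()
    out = []
    for i in range(1, n + 1):
        atoms = [a for a in range(topo.n_atoms) if topo.unit_membership[a] == i]
        unit_com = com([c[a] for a in atoms], [m[a] for a in atoms])
        out.append(dist(unit_com, c[topo.role_index(_nxt(i, 3, n), "O4")]))
    return out


def d4(conf, topo):
    c = conf.coords.tolist()
    m = topo.masses.tolist()
    hp_atoms = {a for g in topo.hp_groups for a in g.atoms}
    ring = [a for a in range(topo.n_atoms) if a not in hp_atoms]
    ring_com = com([c[a] for a in ring], [m[a] for a in ring])
    out = []
    for g in topo.hp_groups:
        hp_com = com([c[a] for a in g.atoms], [m[a] for a in g.atoms])
        out.append(dist(ring_com, hp_com))
    return out


def theta(conf, topo):
    n = topo.n_units
    c = conf.coords.tolist()
    out = []
    for i in range(1, n + 1):
        j = _nxt(i, 1, n)
        v = c[topo.role_index(j, "C2")]
        a = c[topo.role_index(i, "C6")]
        b = c[topo.role_index(j, "C6")]
        u1 = [a[k] - v[k] for k in range(3)]
        u2 = [b[k] - v[k] for k in range(3)]
        dot = sum(x * y for x, y in zip(u1, u2))
        cosang = dot / (math.sqrt(sum(x * x for x in u1)) * math.sqrt(sum(x * x for x in u2)))
        out.append(math.degrees(math.acos(max(-1.0, min(1.0, cosang)))))
    return out


def rg(conf, topo):
    c = conf.coords.tolist()
    m = topo.masses.tolist()
    centre = com(c, m)
    num = sum(mi * sum((ci[k] - centre[k]) ** 2 for k in range(3)) for mi, ci in zip(m, c))
    return math.sqrt(num / sum(m))


def circularity(conf, topo):
    values = d3(conf, topo)
    return min(values) / max(values)
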