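"""Independent oracles used by the test suite.

These deliberately re-derive results with brute-force code paths
(plain loops, exhaustive enumeration) separate from the package
implementation they check.
"""

import numpy as np

from trivasc.trace_io import VesselPath
from trivasc.vessel_graph import build_network

AXIAL_CLASS_OF_CONTACT = {
    frozenset({"S", "I"}): "SI_connecting",
    frozenset({"I", "D"}): "ID_connecting",
    frozenset({"S", "I", "D"}): "SID_connecting",
    frozenset({"S", "D"}): "SD_connecting",
}


def _interior_len(poly, si, id_):
    """Arclength of a polyline inside two z intervals, by direct loops."""
    total = 0.0
    for a, b in zip(poly[:-1], poly[1:]):
        leg = float(np.linalg.norm(b - a))
        z1, z2 = sorted((a[2], b[2]))
        if z2 - z1 < 1e-12:
            for lo, hi in (si, id_):
                if lo <= z1 < hi:
                    total += leg
            continue
        for lo, hi in (si, id_):
            ov = min(z2, hi) - max(z1, lo)
            if ov > 0:
                total += leg * ov / (z2 - z1)
    return total


def axial_oracle(network, partition, interior_frac=0.5):
    """Exhaustive contact-set enumeration of axial chains.

    Independent of the package implementation: candidate selection,
    chain growing (repeated set expansion) and slab contact are all
    recomputed with plain loops.
    """
    si = partition.layer_bounds["SI"]
    id_ = partition.layer_bounds["ID"]
    slabs = partition.plexus_slabs

    def in_slab(z):
        return {
            name for name, (lo, hi) in slabs.items() if lo <= z <= hi
        }

    candidates = []
    for seg in network.segments:
        total = sum(
            float(np.linalg.norm(b - a))
            for a, b in zip(seg.polyline[:-1], seg.polyline[1:])
        )
        if _interior_len(seg.polyline, si, id_) >= interior_frac * total * (
            1 - 1e-12
        ):
            candidates.append(seg)

    # grow chains by repeated expansion through non-slab shared nodes
    remaining = list(candidates)
    chains = []
    while remaining:
        chain = {remaining.pop(0).segment_id}
        changed = True
        while changed:
            changed = False
            for seg in list(remaining):
                for other_id in chain:
                    other = next(
                        s for s in candidates if s.segment_id == other_id
                    )
                    shared = set(seg.end_nodes) & set(other.end_nodes)
                    if any(
                        not in_slab(network.nodes[nid].position[2])
                        for nid in shared
                    ):
                        chain.add(seg.segment_id)
                        remaining.remove(seg)
                        changed = True
                        break
                if changed:
                    break
        chains.append(chain)

    counts = {c: 0 for c in (
        "SI_connecting", "ID_connecting", "SID_connecting", "SD_connecting",
        "inter_plexus_branching",
    )}
    for chain in chains:
        contact = set()
        for sid in chain:
            seg = next(s for s in candidates if s.segment_id == sid)
            for p in seg.polyline:
                contact |= in_slab(float(p[2]))
        cls = AXIAL_CLASS_OF_CONTACT.get(frozenset(contact))
        if cls is not None:
            counts[cls] += 1
    for node in network.nodes.values():
        if node.degree >= 3:
            z = node.position[2]
            if si[0] <= z < si[1] or id_[0] <= z < id_[1]:
                counts["inter_plexus_branching"] += 1
    return counts


def random_small_network(rng, z_max=95.0, max_segments=10):
    """A random network of <= ``max_segments`` short paths, some chained."""
    n = int(rng.integers(1, max_segments + 1))
    paths = []
    bank = []
    for i in range(n):
        if bank and rng.random() < 0.5:
            start = bank[int(rng.integers(len(bank)))]
        else:
            start = np.array(
                [rng.uniform(0, 300), rng.uniform(0, 300), rng.uniform(0, z_max)]
            )
        end = np.array(
            [
                start[0] + rng.uniform(-30, 30),
                start[1] + rng.uniform(-30, 30),
                rng.uniform(0, z_max),
            ]
        )
        if np.linalg.norm(end - start) < 2.0:
            end = end + np.array([5.0, 0.0, 3.0])
        nv = int(rng.integers(2, 6))
        pts = np.linspace(start, end, nv)
        paths.append(VesselPath(f"r{i}", pts))
        bank.extend([start, end])
    return build_network(paths, merge_tol_um=1.0)


def zncc_peak(frame, template):
    """Brute-force zero-normalized cross-correlation argmax (double loop)."""
    th, tw = template.shape
    fh, fw = frame.shape
    t = template - template.mean()
    tnorm = np.sqrt(np.sum(t**2))
    best, arg = -2.0, (0, 0)
    for r in range(fh - th + 1):
        for c in range(fw - tw + 1):
            patch = frame[r : r + th, c : c + tw]
            p = patch - patch.mean()
            denom = np.sqrt(np.sum(p**2)) * tnorm
            val = 0.0 if denom == 0 else float(np.sum(p * t) / denom)
            if val > best:
                best, arg = val, (r, c)
    return best, arg
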