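import random

import pytest

from tirscape.domain_assembly import DomainHit


def random_hit_set(seed: int, n_max: int = 50, protein_id: str = "p1"):
    """Random same-protein hit set for merge-oracle comparisons."""
    rng = random.Random(seed)
    n = rng.randint(0, n_max)
    hits = []
    for i in range(n):
        start = rng.randint(1, 500)
        length = rng.randint(1, 200)
        hits.append(
            DomainHit(
                protein_id=protein_id,
                hmm_name=f"hmm{rng.randint(1, 6)}",
                domain_class=rng.choice(["TIR", "NBARC", "LRR", "TPR"]),
                env_start=start,
                env_end=start + length - 1,
                evalue=rng.choice([0.0, 10 ** rng.uniform(-30, -2)]),
            )
        )
    return hits


def merge_oracle(hits, max_overlap=20):
    """Exhaustive O(n^2) cluster-and-select reference for the redundancy merge.

    Builds the over-overlap graph per domain class by brute force, finds
    connected components by repeated expansion, and keeps the best hit of
    each component under the (evalue, longer envelope, hmm_name) order.
    """
    def overlap(a, b):
        return min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1

    survivors = []
    classes = {h.domain_class for h in hits}
    for cls in classes:
        members = [h for h in hits if h.domain_class == cls]
        unassigned = list(range(len(members)))
        while unassigned:
            comp = {unassigned.pop(0)}
            changed = True
            while changed:
                changed = False
                for i in list(unassigned):
                    if any(
                        overlap(members[i], members[j]) > max_overlap for j in comp
                    ):
                        comp.add(i)
                        unassigned.remove(i)
                        changed = True
            best = min(
                (members[i] for i in comp),
                key=lambda h: (h.evalue, -(h.env_end - h.env_start + 1), h.hmm_name),
            )
            survivors.append(best)
    return sorted(survivors, key=lambda h: (h.env_start, h.env_end, h.hmm_name))


@pytest.fixture
def tiny_hit_fixture(tmp_path):
    """3-row TSV hit table with known fields plus one above-cutoff row."""
    path = tmp_path / "hits.tsv"
    rows = [
        ("protA", "TIR_hmm1", 10, 150, 0.005, 400),
        ("protA", "NBARC_hmm", 200, 390, 1e-20, 400),
        ("protB", "TIR_hmm2", 5, 80, 0.0001, 200),
        ("protB", "LRR_hmm", 90, 150, 0.02, 200),  # above the 0.01 cutoff
    ]
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return path, rows
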