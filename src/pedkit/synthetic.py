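"""Fixture pedigrees, random pedigree simulation, and a gene-dropping oracle.

The gene-dropping simulator is an independent check on the recursive kinship
computation: founder alleles get unique labels, alleles are transmitted by
Mendelian rules (with X hemizygosity and monozygotic-twin genotype copying),
and the kinship coefficient is estimated as the probability that one allele
sampled at random from each of two individuals is identical by descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .model import (
    IndividualRecord,
    Pedigree,
    RelCode,
    Relationship,
    Sex,
)

__all__ = [
    "fixtures",
    "PedigreeSimConfig",
    "generate_random_pedigree",
    "GeneDropEstimate",
    "gene_drop_kinship",
]


def _rec(iid, dad=None, mom=None, sex=Sex.UNKNOWN, famid="1", **kw):
    return IndividualRecord(id=iid, dadid=dad, momid=mom, famid=famid,
                           sex=sex, **kw)


def fixtures() -> dict:
    """Canonical small pedigrees used throughout the test-suite.

    Returns a dict of named :class:`Pedigree` objects:

    * ``trio`` — father, mother, one child;
    * ``nuclear`` — founder couple with three children;
    * ``first_cousins`` — grandparent couple G1 x G2 with children A and B;
      A x SA -> C, B x SB -> D; C and D are first cousins (K = 0.0625);
    * ``sib_mating_loop`` — full sibs mate and have one child (the child's
      self-kinship is 0.625);
    * ``cross_generation`` — a mating between individuals two generations
      apart, both with parents in the pedigree;
    * ``twins`` — one monozygotic and one dizygotic twin pair;
    * ``two_families`` — two disjoint trios (all cross-family kinship 0).
    """
    out = {}
    out["trio"] = Pedigree([
        _rec("F", sex=Sex.MALE),
        _rec("M", sex=Sex.FEMALE),
        _rec("C", "F", "M", Sex.FEMALE),
    ])
    out["nuclear"] = Pedigree([
        _rec("F", sex=Sex.MALE),
        _rec("M", sex=Sex.FEMALE),
        _rec("S1", "F", "M", Sex.MALE),
        _rec("S2", "F", "M", Sex.FEMALE),
        _rec("S3", "F", "M", Sex.MALE),
    ])
    out["first_cousins"] = Pedigree([
        _rec("G1", sex=Sex.MALE),
        _rec("G2", sex=Sex.FEMALE),
        _rec("A", "G1", "G2", Sex.MALE),
        _rec("B", "G1", "G2", Sex.FEMALE),
        _rec("SA", sex=Sex.FEMALE),
        _rec("SB", sex=Sex.MALE),
        _rec("C", "A", "SA", Sex.FEMALE),
        _rec("D", "SB", "B", Sex.MALE),
    ])
    out["sib_mating_loop"] = Pedigree([
        _rec("F", sex=Sex.MALE),
        _rec("M", sex=Sex.FEMALE),
        _rec("S1", "F", "M", Sex.MALE),
        _rec("S2", "F", "M", Sex.FEMALE),
        _rec("C", "S1", "S2", Sex.FEMALE),
    ])
    # O (gen 1) mates K (gen 3): both have pedigree parents, so their
    # generations cannot be equalized and spouse alignment must be bypassed.
    out["cross_generation"] = Pedigree([
        _rec("A", sex=Sex.MALE),
        _rec("B", sex=Sex.FEMALE),
        _rec("O", "A", "B", Sex.MALE),
        _rec("C", sex=Sex.MALE),
        _rec("D", sex=Sex.FEMALE),
        _rec("E", "C", "D", Sex.MALE),
        _rec("F", sex=Sex.FEMALE),
        _rec("G", "E", "F", Sex.FEMALE),
        _rec("H", sex=Sex.MALE),
        _rec("K", "H", "G", Sex.FEMALE),
        _rec("Z", "O", "K", Sex.MALE),
    ])
    out["twins"] = Pedigree(
        [
            _rec("F", sex=Sex.MALE),
            _rec("M", sex=Sex.FEMALE),
            _rec("T1", "F", "M", Sex.MALE),
            _rec("T2", "F", "M", Sex.MALE),
            _rec("D1", "F", "M", Sex.FEMALE),
            _rec("D2", "F", "M", Sex.MALE),
        ],
        [
            Relationship("T1", "T2", RelCode.MZ_TWIN),
            Relationship("D1", "D2", RelCode.DZ_TWIN),
        ],
    )
    out["two_families"] = Pedigree([
        _rec("F", sex=Sex.MALE, famid="1"),
        _rec("M", sex=Sex.FEMALE, famid="1"),
        _rec("C", "F", "M", Sex.MALE, famid="1"),
        _rec("F", sex=Sex.MALE, famid="2"),
        _rec("M", sex=Sex.FEMALE, famid="2"),
        _rec("C", "F", "M", Sex.FEMALE, famid="2"),
    ])
    return out


@dataclass
class PedigreeSimConfig:
    """Forward-in-time pedigree simulation parameters.

    Defaults describe a modest three-generation breeding-colony-like
    pedigree: eight founders, sibship sizes Poisson with mean 2.5, most
    adults mating, occasional consanguineous matings and a realistic
    twinning rate (about 2% of birth events, one third monozygotic).
    """

    n_founders: int = 8
    n_generations: int = 3
    mean_sibship: float = 2.5
    mating_prob: float = 0.8
    loop_injection_prob: float = 0.05
    twin_prob: float = 0.02
    mz_fraction: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2 or self.n_generations < 1:
            raise ValueError("need at least 2 founders and 1 generation")
        for name in ("mating_prob", "loop_injection_prob",
                     "twin_prob", "mz_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_sibship <= 0:
            raise ValueError("mean_sibship must be positive")


def generate_random_pedigree(config: PedigreeSimConfig) -> Pedigree:
    """Simulate a random pedigree; always validates cleanly.

    Founders mate at random; each mating produces a Poisson number of
    children; with probability ``loop_injection_prob`` a male takes a
    related mate (creating a consanguinity loop), otherwise an unrelated
    female of his generation or, failing that, a new married-in founder.
    Twin birth events add MZ/DZ relationship rows.  Reproducible by seed.
    """
    rng = np.random.default_rng(config.seed)
    counter = [0]

    def new_id():
        counter[0] += 1
        return f"I{counter[0]}"

    records: list = []
    rels: list = []
    ancestors: dict = {}

    def add(iid, dad, mom, sex):
        records.append(_rec(iid, dad, mom, sex))
        anc = {iid}
        if dad is not None:
            anc |= ancestors[dad] | ancestors[mom]
        ancestors[iid] = anc
        return iid

    current = []
    for _ in range(config.n_founders):
        sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        current.append((add(new_id(), None, None, sex), sex))

    for _ in range(config.n_generations):
        males = [i for i, s in current if s is Sex.MALE]
        females = [i for i, s in current if s is Sex.FEMALE]
        used: set = set()
        next_gen = []
        for male in males:
            if rng.random() >= config.mating_prob:
                continue
            related = [f for f in females if f not in used
                       and ancestors[male] & ancestors[f]]
            unrelated = [f for f in females if f not in used
                         and not (ancestors[male] & ancestors[f])]
            if related and rng.random() < config.loop_injection_prob:
                mate = related[rng.integers(len(related))]
            elif unrelated:
                mate = unrelated[rng.integers(len(unrelated))]
            else:
                mate = add(new_id(), None, None, Sex.FEMALE)
            used.add(mate)
            n_children = int(rng.poisson(config.mean_sibship))
            born = 0
            while born < n_children:
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                child = add(new_id(), male, mate, sex)
                next_gen.append((child, sex))
                born += 1
                if born < n_children and rng.random() < config.twin_prob:
                    mz = rng.random() < config.mz_fraction
                    twin_sex = sex if mz else (
                        Sex.MALE if rng.random() < 0.5 else Sex.FEMALE)
                    twin = add(new_id(), male, mate, twin_sex)
                    next_gen.append((twin, twin_sex))
                    born += 1
                    rels.append(Relationship(
                        child, twin,
                        RelCode.MZ_TWIN if mz else RelCode.DZ_TWIN))
        current = next_gen
        if not current:
            break
    return Pedigree(records, rels)


@dataclass
class GeneDropEstimate:
    """Monte-Carlo kinship estimates with binomial standard errors."""

    ids: tuple
    estimate: np.ndarray
    n_reps: int
    mode: str
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {key: i for i, key in enumerate(self.ids)}

    def se(self) -> np.ndarray:
        p = self.estimate
        return np.sqrt(p * (1.0 - p) / self.n_reps)

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.estimate[self._index[i], self._index[j]])


def _mz_rep_map(pedigree: Pedigree) -> dict:
    from .kinship import _mz_groups  # shared grouping logic

    rep = {}
    for famid in pedigree.famids:
        for group in _mz_groups(pedigree, famid):
            for key in group[1:]:
                rep[key] = group[0]
    return rep


def gene_drop_kinship(pedigree: Pedigree, mode: str = "autosome",
                      n_reps: int = 200_000,
                      seed: int = 0,
                      mz_adjust: bool = True) -> GeneDropEstimate:
    """Estimate kinship coefficients by gene-dropping simulation.

    Per replicate every founder receives unique allele labels (two autosomal
    copies; for X, two in females and one in males), alleles are transmitted
    Mendelianly (a son's X always comes from his mother; MZ twins copy their
    representative's genotype), and for each pair one random allele per
    individual is compared.  The estimate for a pair is the fraction of
    replicates in which the sampled alleles were identical by descent, with
    binomial standard error sqrt(p(1-p)/n).  Self-kinship draws the two
    alleles independently, so it estimates (1+F)/2.
    """
    from .kinship import generation_order

    if mode not in ("autosome", "X"):
        raise ValueError(f"unknown kinship mode {mode!r}")
    rng = np.random.default_rng(seed)
    keys = [rec.key for rec in pedigree.records]
    pos = {key: i for i, key in enumerate(keys)}
    n = len(keys)
    # alleles[i, c, r]: allele label of copy c of individual i in replicate r
    alleles = np.zeros((n, 2, n_reps), dtype=np.int32)
    rep_map = _mz_rep_map(pedigree) if mz_adjust else {}

    label = 0
    for famid in pedigree.famids:
        for key in generation_order(pedigree, famid):
            i = pos[key]
            if key in rep_map:
                alleles[i] = alleles[pos[rep_map[key]]]
                continue
            rec = pedigree[key]
            parents = pedigree.parents_of(key)
            if mode == "autosome":
                if not parents:
                    alleles[i, 0] = label
                    alleles[i, 1] = label + 1
                    label += 2
                else:
                    fi, mi = pos[parents[0]], pos[parents[1]]
                    pick = rng.integers(0, 2, size=n_reps)
                    alleles[i, 0] = alleles[fi, pick, np.arange(n_reps)]
                    pick = rng.integers(0, 2, size=n_reps)
                    alleles[i, 1] = alleles[mi, pick, np.arange(n_reps)]
            else:
                if rec.sex is Sex.UNKNOWN:
                    raise ValueError(
                        f"X-linked gene dropping requires known sex: "
                        f"{key[1]!r} has unknown sex")
                if not parents:
                    if rec.sex is Sex.MALE:
                        alleles[i, 0] = alleles[i, 1] = label
                        label += 1
                    else:
                        alleles[i, 0] = label
                        alleles[i, 1] = label + 1
                        label += 2
                else:
                    fi, mi = pos[parents[0]], pos[parents[1]]
                    pick = rng.integers(0, 2, size=n_reps)
                    from_mother = alleles[mi, pick, np.arange(n_reps)]
                    if rec.sex is Sex.MALE:
                        # hemizygous: the single X comes from the mother
                        alleles[i, 0] = alleles[i, 1] = from_mother
                    else:
                        alleles[i, 0] = alleles[fi, 0]  # father's single X
                        alleles[i, 1] = from_mother

    estimate = np.zeros((n, n))
    reps = np.arange(n_reps)
    for i in range(n):
        for j in range(i, n):
            if keys[i][0] != keys[j][0]:
                continue  # different families share no founders: exactly 0
            a = alleles[i, rng.integers(0, 2, size=n_reps), reps]
            b = alleles[j, rng.integers(0, 2, size=n_reps), reps]
            estimate[i, j] = estimate[j, i] = np.mean(a == b)
    return GeneDropEstimate(tuple(keys), estimate, n_reps, mode)
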