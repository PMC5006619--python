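"""Construction and serialisation of retroelement consensus libraries.

`example_library` builds a small seeded library of synthetic consensus
elements that exercise every structural feature the annotator reads:
a DGLT-A-like chromovirus relative with a canonical primer-binding-site
(PBS) junction and a short integrase carboxy-terminal extension; two
Skipper-like chromoviruses (polypyrimidine junction, long IN-CTD with a
group I or group II chromo domain); and a TRE5-like non-LTR element.
Real libraries are read/written as JSON with per-element metadata.
"""
from __future__ import annotations

import json
from typing import Dict, Optional

import numpy as np

from .intervals import ConsensusElement
from .simulate import build_ltr_consensus, build_nonltr_consensus, reverse_translate

PBS_LINKER = "AT" + "TGGCGACATCGTCTTTC"
PPY_LINKER = "TTCTTTTCTTTCTTTTC"

# residues used for random protein stretches; P is excluded so that no
# spurious G-P-[Y/F] motif can arise downstream of the intended one
_AA_SAFE = "ACDEFGHIKLMNQRSTVW"


def _random_dna(n: int, rng: np.random.Generator, gc: float = 0.35) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def _random_protein(n: int, rng: np.random.Generator) -> str:
    return "".join(_AA_SAFE[i] for i in rng.integers(0, len(_AA_SAFE), n))


def _ltr_family(name: str, rng: np.random.Generator, ltr_len: int,
                linker: str, core_len: int, gpyf: str, ctd: str) -> ConsensusElement:
    protein = _random_protein(core_len, rng) + gpyf + ctd
    orf_dna = reverse_translate(protein) + "TAA"
    elem = build_ltr_consensus(
        name, ltr=_random_dna(ltr_len, rng), junction_linker=linker,
        internal_orf=orf_dna,
    )
    elem.domain_annotations = [("IN_core_end", (core_len, core_len + 3))]
    return elem


def example_library(seed: int = 0) -> Dict[str, ConsensusElement]:
    """Seeded synthetic consensus library (four families)."""
    # representative true CHD = first row of the packaged profile alignment
    from importlib import resources
    data = json.loads(resources.files("retrotarget.data")
                      .joinpath("chd_profile_synthetic.json").read_text())
    chd = data["rows"][0]
    cage = data["cage_columns"]
    chd2 = list(chd)
    chd2[cage[0]] = "S"
    chd2[cage[2]] = "E"
    chd2 = "".join(chd2)

    rng = np.random.default_rng([seed, 101])
    lib = {}
    # DGLT-A-like: PBS junction, 32-aa IN-CTD, no CHD
    lib["DGLTA_like"] = _ltr_family(
        "DGLTA_like", rng, ltr_len=265, linker=PBS_LINKER,
        core_len=900, gpyf="GPY", ctd=_random_protein(32, rng))
    # Skipper-like: PPy junction, 183-aa IN-CTD containing a group I CHD
    rng = np.random.default_rng([seed, 102])
    ctd1 = _random_protein(60, rng) + chd + _random_protein(183 - 60 - len(chd), rng)
    lib["Skipper_like"] = _ltr_family(
        "Skipper_like", rng, ltr_len=390, linker=PPY_LINKER,
        core_len=1000, gpyf="GPF", ctd=ctd1)
    # Skipper2-like: PBS junction but a group II CHD (diverged cage 1 and 3)
    rng = np.random.default_rng([seed, 103])
    ctd2 = _random_protein(40, rng) + chd2 + _random_protein(26, rng)
    lib["Skipper2_like"] = _ltr_family(
        "Skipper2_like", rng, ltr_len=310, linker=PBS_LINKER,
        core_len=950, gpyf="GPY", ctd=ctd2)
    # TRE5-like: non-LTR, UTRs + single ORF + poly(A)
    rng = np.random.default_rng([seed, 104])
    orf = reverse_translate(_random_protein(600, rng)) + "TAA"
    lib["TRE5_like"] = build_nonltr_consensus(
        "TRE5_like", utr5=_random_dna(80, rng), orf_dna=orf,
        polya_len=20, utr3=_random_dna(30, rng))
    return lib


# ---------------------------------------------------------------------------
# JSON (de)serialisation

def write_library(path, library: Dict[str, ConsensusElement]) -> None:
    data = {}
    for name, el in sorted(library.items()):
        data[name] = {
            "sequence": el.sequence,
            "element_class": el.element_class,
            "ltr_spans": [list(s) for s in el.ltr_spans] if el.ltr_spans else None,
            "orf_spans": [list(s) for s in el.orf_spans],
            "domain_annotations": [[n, list(s)] for n, s in el.domain_annotations],
        }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_library(path) -> Dict[str, ConsensusElement]:
    with open(path) as fh:
        data = json.load(fh)
    lib = {}
    for name, d in data.items():
        lib[name] = ConsensusElement(
            name=name,
            sequence=d["sequence"],
            element_class=d["element_class"],
            ltr_spans=tuple(tuple(s) for s in d["ltr_spans"]) if d.get("ltr_spans") else None,
            orf_spans=[tuple(s) for s in d.get("orf_spans", [])],
            domain_annotations=[(n, tuple(s)) for n, s in d.get("domain_annotations", [])],
        )
    return lib
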