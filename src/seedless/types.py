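"""Shared enumerations for generations, genotypes and phenotypes.

The marker genotype refers to the *INO* locus: ``HOM_WT`` carries two
wild-type alleles, ``HOM_DEL`` two copies of the deletion allele.  The
phenotype is the seed trait, fully recessive for seedlessness.
"""

from __future__ import annotations

from enum import Enum


class Generation(str, Enum):
    F1 = "F1"
    F2 = "F2"
    BC_M = "BC_M"      # backcross to the wild-type parent
    BC_BS = "BC_Bs"    # backcross to the seedless mutant parent

    @classmethod
    def coerce(cls, value: "Generation | str") -> "Generation":
        if isinstance(value, cls):
            return value
        for member in cls:
            if member.value.lower() == str(value).lower():
                return member
        raise ValueError(f"unknown generation: {value!r}")


class Genotype(str, Enum):
    HOM_WT = "hom_wt"    # INO / INO
    HET = "het"          # INO / ino
    HOM_DEL = "hom_del"  # ino / ino
    NO_CALL = "no_call"

    @classmethod
    def coerce(cls, value: "Genotype | str") -> "Genotype":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


class Phenotype(str, Enum):
    SEEDED = "seeded"
    SEEDLESS = "seedless"
    UNKNOWN = "unknown"

    @classmethod
    def coerce(cls, value: "Phenotype | str") -> "Phenotype":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())
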