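"""Physical constants and unit conventions used across the package.

Lengths inside oxDNA-format files are in oxDNA simulation units (su);
every user-facing length is in nanometers.  Angles are degrees in all
public outputs and radians internally.
"""

#: nanometers per oxDNA simulation length unit
NM_PER_SU: float = 0.8518

#: helical rise of B-form DNA, nm per base pair
RISE_NM_PER_BP: float = 0.34

#: diameter of a B-form DNA duplex, nm
DUPLEX_WIDTH_NM: float = 2.0

#: Watson-Crick complement table
WC_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    try:
        return "".join(WC_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence: {exc.args[0]!r}") from None
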