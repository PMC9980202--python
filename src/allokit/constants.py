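"""Physical constants and shared label sets."""

# Boltzmann constant in kcal/(mol*K)
KB = 0.001987

# Condition labels used for classification: modulator-free/bound pairs for
# inactive (antagonist) and active (agonist) receptor states, plus the
# apo/NAM pair used for ligand-free systems.
CONDITION_LABELS = (
    "Antagonist",
    "AntagonistNAM",
    "Agonist",
    "AgonistPAM",
    "Apo",
    "NAM",
)

ROLE_RECEPTOR = "receptor"
ROLE_ORTHOSTERIC = "orthosteric_ligand"
ROLE_MODULATOR = "allosteric_modulator"
ROLES = (ROLE_RECEPTOR, ROLE_ORTHOSTERIC, ROLE_MODULATOR)
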