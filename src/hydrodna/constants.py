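"""Physical constants (CODATA 2018) and analysis defaults.

All coordinates are in Angstrom, entropies in J K^-1 mol^-1 and
temperatures in Kelvin throughout the package.  Every numeric threshold
used by an analysis stage lives here (or in :class:`hydrodna.pipeline.RunConfig`,
which echoes these defaults) so that no stage carries a hidden constant.
"""

import math

# --- CODATA 2018 physical constants (SI) ---------------------------------
BOLTZMANN_J_PER_K = 1.380649e-23        # k_B
PLANCK_HBAR_J_S = 1.054571817e-34       # reduced Planck constant
GAS_CONSTANT_J_PER_K_MOL = 8.314462618  # R
ATOMIC_MASS_KG = 1.66053906660e-27      # 1 u in kg
EULER_E = math.e                        # Euler's number (enters Schlitter's bound)

ANGSTROM_M = 1.0e-10

# Mass of a water molecule (u).  The translational-entropy proxy treats the
# molecule as a point particle at its oxygen position.
WATER_MASS_U = 18.01528

# --- analysis defaults ----------------------------------------------------
# Interfacial-water cutoffs: 5 A applied instantaneously per frame,
# 4 A applied once to site mean positions against a reference structure.
INTERFACE_CUTOFF_INSTANTANEOUS_A = 5.0
INTERFACE_CUTOFF_MEAN_POSITION_A = 4.0

# A water site counts as low-mobility when its oxygen RMSF is strictly
# below this threshold.
RMSF_LOW_MOBILITY_A = 1.9

# Hydrogen-bond geometry: donor-acceptor distance strictly below the
# cutoff and donor-hydrogen-acceptor angle strictly above the minimum.
HBOND_DA_CUTOFF_A = 3.0
HBOND_DHA_MIN_DEG = 120.0

# Water bridges of order 0 (direct) up to this many intervening waters.
BRIDGE_MAX_ORDER = 3
# A residue-nucleotide contact is stable when bridged in strictly more
# than this fraction of frames.
BRIDGE_STABILITY_FRACTION = 0.05

# Solvent-entropy bookkeeping.
TEMPERATURE_K = 298.15
S_BULK_J_PER_K_MOL = 118.0  # mean bulk-water first-order entropy reference

# SELEX enrichment.
REFERENCE_KMER = "TAAACG"

# Default residue-name -> entity-class rules for PDB input.
WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "OPC"})
ION_RESIDUE_NAMES = frozenset({"NA", "CL", "K", "MG", "CA", "ZN", "NA+", "CL-"})
DNA_RESIDUE_NAMES = frozenset(
    {"DA", "DT", "DG", "DC", "DI", "DU", "A", "T", "G", "C", "U"}
)
PROTEIN_RESIDUE_NAMES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL", "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
    }
)
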