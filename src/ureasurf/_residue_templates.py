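"""Ideal-geometry heavy-atom coordinates of the 20 standard amino acids.

Reference conformers from the PDB chemical component dictionary (CCD) ideal
coordinate sets; heavy atoms only, Angstrom.  Each entry maps a three-letter
residue name to a list of (atom_name, element, x, y, z).  Used to graft side
chains onto ideal backbones; regenerate with scripts/freeze_residue_templates.py.
"""

IDEAL_RESIDUES = {
    "ALA": [
        ("N", "N", -0.966, 0.493, 1.500),
        ("CA", "C", 0.257, 0.418, 0.692),
        ("C", "C", -0.094, 0.017, -0.716),
        ("O", "O", -1.056, -0.682, -0.923),
        ("CB", "C", 1.204, -0.620, 1.296),
        ("OXT", "O", 0.661, 0.439, -1.742),
    ],
    "CYS": [
        ("N", "N", 1.585, 0.483, -0.081),
        ("CA", "C", 0.141, 0.450, 0.186),
        ("C", "C", -0.095, 0.006, 1.606),
        ("O", "O", 0.685, -0.742, 2.143),
        ("CB", "C", -0.533, -0.530, -0.774),
        ("SG", "S", -0.247, 0.004, -2.484),
        ("OXT", "O", -1.174, 0.443, 2.275),
    ],
    "ASP": [
        ("N", "N", -0.317, 1.688, 0.066),
        ("CA", "C", -0.470, 0.286, -0.344),
        ("C", "C", -1.868, -0.180, -0.029),
        ("O", "O", -2.534, 0.415, 0.786),
        ("CB", "C", 0.539, -0.580, 0.413),
        ("CG", "C", 1.938, -0.195, 0.004),
        ("OD1", "O", 2.109, 0.681, -0.810),
        ("OD2", "O", 2.992, -0.826, 0.543),
        ("OXT", "O", -2.374, -1.256, -0.652),
    ],
    "GLU": [
        ("N", "N", 1.199, 1.867, -0.117),
        ("CA", "C", 1.138, 0.515, 0.453),
        ("C", "C", 2.364, -0.260, 0.041),
        ("O", "O", 3.010, 0.096, -0.916),
        ("CB", "C", -0.113, -0.200, -0.062),
        ("CG", "C", -1.360, 0.517, 0.461),
        ("CD", "C", -2.593, -0.187, -0.046),
        ("OE1", "O", -2.485, -1.161, -0.753),
        ("OE2", "O", -3.811, 0.269, 0.287),
        ("OXT", "O", 2.737, -1.345, 0.737),
    ],
    "PHE": [
        ("N", "N", 1.317, 0.962, 1.014),
        ("CA", "C", -0.020, 0.426, 1.300),
        ("C", "C", -0.109, 0.047, 2.756),
        ("O", "O", 0.879, -0.317, 3.346),
        ("CB", "C", -0.270, -0.809, 0.434),
        ("CG", "C", -0.181, -0.430, -1.020),
        ("CD1", "C", 1.031, -0.498, -1.680),
        ("CD2", "C", -1.314, -0.018, -1.698),
        ("CE1", "C", 1.112, -0.150, -3.015),
        ("CE2", "C", -1.231, 0.333, -3.032),
        ("CZ", "C", -0.018, 0.265, -3.691),
        ("OXT", "O", -1.286, 0.113, 3.396),
    ],
    "GLY": [
        ("N", "N", 1.931, 0.090, -0.034),
        ("CA", "C", 0.761, -0.799, -0.008),
        ("C", "C", -0.498, 0.029, -0.005),
        ("O", "O", -0.429, 1.235, -0.023),
        ("OXT", "O", -1.697, -0.574, 0.018),
    ],
    "HIS": [
        ("N", "N", -0.040, -1.210, 0.053),
        ("CA", "C", 1.172, -1.709, 0.652),
        ("C", "C", 1.083, -3.207, 0.905),
        ("O", "O", 0.040, -3.770, 1.222),
        ("CB", "C", 1.484, -0.975, 1.962),
        ("CG", "C", 2.940, -1.060, 2.353),
        ("ND1", "N", 3.380, -2.075, 3.129),
        ("CD2", "C", 3.960, -0.251, 2.046),
        ("CE1", "C", 4.693, -1.908, 3.317),
        ("NE2", "N", 5.058, -0.801, 2.662),
        ("OXT", "O", 2.247, -3.882, 0.744),
    ],
    "ILE": [
        ("N", "N", -1.944, 0.335, -0.343),
        ("CA", "C", -0.487, 0.519, -0.369),
        ("C", "C", 0.066, -0.032, -1.657),
        ("O", "O", -0.484, -0.958, -2.203),
        ("CB", "C", 0.140, -0.219, 0.814),
        ("CG1", "C", -0.421, 0.341, 2.122),
        ("CG2", "C", 1.658, -0.027, 0.788),
        ("CD1", "C", 0.206, -0.397, 3.305),
        ("OXT", "O", 1.171, 0.504, -2.197),
    ],
    "LYS": [
        ("N", "N", 1.422, 1.796, 0.198),
        ("CA", "C", 1.394, 0.355, 0.484),
        ("C", "C", 2.657, -0.284, -0.032),
        ("O", "O", 3.316, 0.275, -0.876),
        ("CB", "C", 0.184, -0.278, -0.206),
        ("CG", "C", -1.102, 0.282, 0.407),
        ("CD", "C", -2.313, -0.351, -0.283),
        ("CE", "C", -3.598, 0.208, 0.329),
        ("NZ", "N", -4.761, -0.400, -0.332),
        ("OXT", "O", 3.050, -1.476, 0.446),
    ],
    "LEU": [
        ("N", "N", -1.661, 0.627, -0.406),
        ("CA", "C", -0.205, 0.441, -0.467),
        ("C", "C", 0.180, -0.055, -1.836),
        ("O", "O", -0.591, -0.731, -2.474),
        ("CB", "C", 0.221, -0.583, 0.585),
        ("CG", "C", -0.170, -0.079, 1.976),
        ("CD1", "C", 0.256, -1.104, 3.029),
        ("CD2", "C", 0.526, 1.254, 2.250),
        ("OXT", "O", 1.382, 0.254, -2.348),
    ],
    "MET": [
        ("N", "N", -1.816, 0.142, -1.166),
        ("CA", "C", -0.392, 0.499, -1.214),
        ("C", "C", 0.206, 0.002, -2.504),
        ("O", "O", -0.236, -0.989, -3.033),
        ("CB", "C", 0.334, -0.145, -0.032),
        ("CG", "C", -0.273, 0.359, 1.277),
        ("SD", "S", 0.589, -0.405, 2.678),
        ("CE", "C", -0.314, 0.353, 4.056),
        ("OXT", "O", 1.232, 0.661, -3.066),
    ],
    "ASN": [
        ("N", "N", -0.293, 1.686, 0.094),
        ("CA", "C", -0.448, 0.292, -0.340),
        ("C", "C", -1.846, -0.179, -0.031),
        ("O", "O", -2.510, 0.402, 0.794),
        ("CB", "C", 0.562, -0.588, 0.401),
        ("CG", "C", 1.960, -0.197, -0.002),
        ("OD1", "O", 2.132, 0.697, -0.804),
        ("ND2", "N", 3.019, -0.841, 0.527),
        ("OXT", "O", -2.353, -1.243, -0.673),
    ],
    "PRO": [
        ("N", "N", -0.816, 1.108, 0.254),
        ("CA", "C", 0.001, -0.107, 0.509),
        ("C", "C", 1.408, 0.091, 0.005),
        ("O", "O", 1.650, 0.980, -0.777),
        ("CB", "C", -0.703, -1.227, -0.286),
        ("CG", "C", -2.163, -0.753, -0.439),
        ("CD", "C", -2.218, 0.614, 0.276),
        ("OXT", "O", 2.391, -0.721, 0.424),
    ],
    "GLN": [
        ("N", "N", 1.858, -0.148, 1.125),
        ("CA", "C", 0.517, 0.451, 1.112),
        ("C", "C", -0.236, 0.022, 2.344),
        ("O", "O", -0.005, -1.049, 2.851),
        ("CB", "C", -0.236, -0.013, -0.135),
        ("CG", "C", 0.529, 0.421, -1.385),
        ("CD", "C", -0.213, -0.036, -2.614),
        ("OE1", "O", -1.252, -0.650, -2.500),
        ("NE2", "N", 0.277, 0.236, -3.839),
        ("OXT", "O", -1.165, 0.831, 2.878),
    ],
    "ARG": [
        ("N", "N", -0.469, 1.110, -0.993),
        ("CA", "C", 0.004, 2.294, -1.708),
        ("C", "C", -0.907, 2.521, -2.901),
        ("O", "O", -1.827, 1.789, -3.242),
        ("CB", "C", 1.475, 2.150, -2.127),
        ("CG", "C", 1.745, 1.017, -3.130),
        ("CD", "C", 3.210, 0.954, -3.557),
        ("NE", "N", 4.071, 0.726, -2.421),
        ("CZ", "C", 5.469, 0.624, -2.528),
        ("NH1", "N", 6.259, 0.404, -1.405),
        ("NH2", "N", 6.078, 0.744, -3.773),
        ("OXT", "O", -0.588, 3.659, -3.574),
    ],
    "SER": [
        ("N", "N", 1.525, 0.493, -0.608),
        ("CA", "C", 0.100, 0.469, -0.252),
        ("C", "C", -0.053, 0.004, 1.173),
        ("O", "O", 0.751, -0.760, 1.649),
        ("CB", "C", -0.642, -0.489, -1.184),
        ("OG", "O", -0.496, -0.049, -2.535),
        ("OXT", "O", -1.084, 0.440, 1.913),
    ],
    "THR": [
        ("N", "N", 1.543, -0.702, 0.430),
        ("CA", "C", 0.122, -0.706, 0.056),
        ("C", "C", -0.038, -0.090, -1.309),
        ("O", "O", 0.732, 0.761, -1.683),
        ("CB", "C", -0.675, 0.104, 1.079),
        ("OG1", "O", -0.193, 1.448, 1.103),
        ("CG2", "C", -0.511, -0.521, 2.466),
        ("OXT", "O", -1.039, -0.488, -2.110),
    ],
    "VAL": [
        ("N", "N", 1.564, -0.642, 0.454),
        ("CA", "C", 0.145, -0.698, 0.079),
        ("C", "C", -0.037, -0.093, -1.288),
        ("O", "O", 0.703, 0.784, -1.664),
        ("CB", "C", -0.682, 0.086, 1.098),
        ("CG1", "C", -0.497, -0.528, 2.487),
        ("CG2", "C", -0.218, 1.543, 1.119),
        ("OXT", "O", -1.022, -0.529, -2.089),
    ],
    "TRP": [
        ("N", "N", 1.278, 1.121, 2.059),
        ("CA", "C", -0.008, 0.417, 1.970),
        ("C", "C", -0.490, 0.076, 3.357),
        ("O", "O", 0.308, -0.130, 4.240),
        ("CB", "C", 0.168, -0.868, 1.161),
        ("CG", "C", 0.650, -0.526, -0.225),
        ("CD1", "C", 1.928, -0.418, -0.622),
        ("CD2", "C", -0.186, -0.256, -1.396),
        ("NE1", "N", 1.978, -0.095, -1.951),
        ("CE2", "C", 0.701, 0.014, -2.454),
        ("CE3", "C", -1.564, -0.210, -1.615),
        ("CZ2", "C", 0.190, 0.314, -3.712),
        ("CZ3", "C", -2.044, 0.086, -2.859),
        ("CH2", "C", -1.173, 0.348, -3.907),
        ("OXT", "O", -1.806, 0.001, 3.610),
    ],
    "TYR": [
        ("N", "N", 1.320, 0.952, 1.428),
        ("CA", "C", -0.018, 0.429, 1.734),
        ("C", "C", -0.103, 0.094, 3.201),
        ("O", "O", 0.886, -0.254, 3.799),
        ("CB", "C", -0.274, -0.831, 0.907),
        ("CG", "C", -0.189, -0.496, -0.559),
        ("CD1", "C", 1.022, -0.589, -1.219),
        ("CD2", "C", -1.324, -0.102, -1.244),
        ("CE1", "C", 1.103, -0.282, -2.563),
        ("CE2", "C", -1.247, 0.210, -2.587),
        ("CZ", "C", -0.032, 0.118, -3.252),
        ("OH", "O", 0.044, 0.420, -4.574),
        ("OXT", "O", -1.279, 0.184, 3.842),
    ],
}
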