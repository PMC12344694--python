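"""Unit system: Å / fs / eV / amu.

All public interfaces use Ångström for length, femtosecond for time,
electron-volt for energy and atomic mass units for mass.  Newton's second
law then reads  a [Å/fs²] = ACC_CONV · F [eV/Å] / m [amu].
"""

# 1 (eV/Å)/amu expressed in Å/fs² (CODATA): 0.00964853 to 6 significant figures
ACC_CONV = 9.648533212e-3

# Boltzmann constant in eV/K
K_B = 8.617333e-5

# kinetic energy in eV:  0.5 * m [amu] * v² [Å²/fs²] / ACC_CONV
EV_PER_AMU_A2_FS2 = 1.0 / ACC_CONV


def kinetic_energy(masses, velocities):
    """Total kinetic energy (eV) of per-atom masses (amu) and velocities (Å/fs)."""
    import numpy as np

    masses = np.asarray(masses, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    return float(0.5 * np.sum(masses * np.sum(velocities**2, axis=-1)) / ACC_CONV)
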