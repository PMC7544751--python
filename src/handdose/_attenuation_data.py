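"""Frozen photon mass-interaction coefficients (cm^2/g).

Fixed 10 keV - 1 MeV grid. Channels: photoelectric,
incoherent (Compton), coherent (Rayleigh), total without
coherent, and mass energy-absorption. Generated file; do
not edit by hand.
"""

import numpy as np

ENERGY_GRID_MEV = np.array([0.01, 0.015, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.1, 0.15, 0.2, 0.3, 0.4,
 0.5, 0.6, 0.8, 1])

DENSITIES_G_CM3 = {
    "air": 0.00120479,
    "water": 1.0,
    "soft_tissue": 1.09,
    "tungsten": 19.3,
}

COMPOSITIONS = {
    "air": {"C": 0.000124, "N": 0.755268, "O": 0.231781, "Ar": 0.012827},
    "water": {"H": 0.111894, "O": 0.888106},
    "soft_tissue": {"H": 0.100588, "C": 0.228250, "N": 0.046420, "O": 0.619002, "Na": 0.000070, "Mg": 0.000060, "P": 0.000330, "S": 0.001590, "Cl": 0.002670, "K": 0.000850, "Ca": 0.000150, "Fe": 0.000010, "Zn": 0.000010},
    "tungsten": {"W": 1.000000},
}

TABLES = {
    "air": {
        "photoelectric": np.array([4.8275, 1.3409, 0.53522, 0.13838, 0.051022, 0.023202, 0.012978,
 0.0029957, 1.481e-05, 1.316e-05, 1.203e-05, 1.05e-05, 9.42e-06,
 8.64e-06, 8.04e-06, 7.06e-06, 0.00010753]),
        "incoherent": np.array([0.19254, 0.18908, 0.18578, 0.17962, 0.17398, 0.1688, 0.16402, 0.1555,
 0.14813, 0.13335, 0.1222, 0.10625, 0.095199, 0.086928, 0.080414,
 0.070633, 0.063492]),
        "coherent": np.array([0.11532, 0.065178, 0.042115, 0.021058, 0.012534, 0.0085233, 0.0060165,
 0.0036099, 0.0024066, 0.001103, 0.00066181, 0.00031085, 0.00018049,
 0.00012033, 8.6236e-05, 5.0137e-05, 3.3091e-05]),
        "total": np.array([5.02, 1.53, 0.721, 0.318, 0.225, 0.192, 0.177, 0.1585, 0.14814,
 0.13337, 0.12221, 0.10626, 0.095208, 0.086937, 0.080422, 0.07064,
 0.0636]),
        "mu_en": np.array([4.8311, 1.3461, 0.54192, 0.14773, 0.062658, 0.036825, 0.028335,
 0.02121, 0.020457, 0.024225, 0.026449, 0.028662, 0.029486, 0.029683,
 0.029561, 0.028872, 0.028047]),
    },
    "water": {
        "photoelectric": np.array([5.0059, 1.3697, 0.54442, 0.13527, 0.049539, 0.020299, 0.0096096,
 0.0018813, 1.641e-05, 1.46e-05, 1.335e-05, 1.165e-05, 1.045e-05,
 9.66e-06, 8.94e-06, 7.85e-06, 9.7212e-05]),
        "incoherent": np.array([0.2141, 0.21025, 0.20658, 0.19973, 0.19346, 0.1877, 0.18239, 0.17292,
 0.16472, 0.14829, 0.13588, 0.11815, 0.10586, 0.096663, 0.089419,
 0.078543, 0.070603]),
        "coherent": np.array([0.115, 0.065, 0.042, 0.021, 0.0125, 0.0085, 0.006, 0.0036, 0.0024,
 0.0011, 0.00066, 0.00031, 0.00018, 0.00012, 8.6e-05, 5e-05, 3.3e-05]),
        "total": np.array([5.22, 1.58, 0.751, 0.335, 0.243, 0.208, 0.192, 0.1748, 0.16473, 0.1483,
 0.13589, 0.11816, 0.10587, 0.096672, 0.089428, 0.07855, 0.0707]),
        "mu_en": np.array([5.0099, 1.3755, 0.55187, 0.14566, 0.062478, 0.035448, 0.026687,
 0.022135, 0.022748, 0.026938, 0.029411, 0.031872, 0.032788, 0.033007,
 0.032872, 0.032105, 0.031165]),
    },
    "soft_tissue": {
        "photoelectric": np.array([4.8254, 1.3166, 0.52178, 0.12796, 0.046202, 0.018504, 0.0084315,
 0.0015792, 1.6229e-05, 1.4454e-05, 1.3217e-05, 1.1534e-05, 1.0345e-05,
 9.5634e-06, 1.5237e-05, 7.7715e-06, 0.00012332]),
        "incoherent": np.array([0.21187, 0.20807, 0.20444, 0.19766, 0.19145, 0.18575, 0.1805, 0.17112,
 0.16301, 0.14675, 0.13447, 0.11692, 0.10476, 0.095659, 0.088491,
 0.077727, 0.06987]),
        "coherent": np.array([0.10891, 0.061558, 0.039776, 0.019888, 0.011838, 0.0080499, 0.0056823,
 0.0034094, 0.0022729, 0.0010418, 0.00062505, 0.00029358, 0.00017047,
 0.00011365, 8.1446e-05, 4.7352e-05, 3.1253e-05]),
        "total": np.array([5.0373, 1.5247, 0.72622, 0.32562, 0.23765, 0.20426, 0.18893, 0.1727,
 0.16302, 0.14676, 0.13448, 0.11694, 0.10477, 0.095669, 0.088506,
 0.077735, 0.069993]),
        "mu_en": np.array([4.8294, 1.3224, 0.52915, 0.13825, 0.059006, 0.033496, 0.025331,
 0.021623, 0.022512, 0.026658, 0.029106, 0.031541, 0.032447, 0.032664,
 0.032537, 0.031772, 0.030869]),
    },
    "tungsten": {
        "photoelectric": np.array([96.755, 138.85, 65.58, 22.585, 10.53, 5.8129, 3.5807, 7.6846, 4.3186,
 1.4735, 0.68587, 0.23812, 0.11574, 0.067704, 0.044457, 0.023704,
 0.014982]),
        "incoherent": np.array([0.15525, 0.15246, 0.1498, 0.14484, 0.14029, 0.13611, 0.13226, 0.12539,
 0.11944, 0.10753, 0.098534, 0.085678, 0.076765, 0.070096, 0.064843,
 0.056956, 0.051198]),
        "coherent": np.array([0.93499, 0.52847, 0.34147, 0.17074, 0.10163, 0.069108, 0.048782,
 0.029269, 0.019513, 0.0089434, 0.005366, 0.0025204, 0.0014635,
 0.00097564, 0.00069921, 0.00040652, 0.0002683]),
        "total": np.array([96.91, 139, 65.73, 22.73, 10.67, 5.949, 3.713, 7.81, 4.438, 1.581,
 0.7844, 0.3238, 0.1925, 0.1378, 0.1093, 0.08066, 0.06618]),
        "mu_en": np.array([96.758, 138.85, 65.586, 22.593, 10.539, 5.8239, 3.5931, 7.6993, 4.335,
 1.493, 0.70718, 0.26123, 0.1395, 0.091633, 0.068288, 0.04698, 0.037511]),
    },
}

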