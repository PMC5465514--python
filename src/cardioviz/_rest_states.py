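"""Packaged quiescent states (generated by scripts/make_rest_states.py).

Each entry is the state vector (layout of cardioviz._tnnp06.VAR_NAMES)
after a 40 s unstimulated relaxation at dt = 0.02 ms from the published
paced steady-state initial conditions of the corresponding cell class."""

REST_STATES = {
    "endo": (
        -86.29477748256308,
        0.0013676038678040897,
        0.7729197598867561,
        0.7729087782891055,
        0.00018160448989795196,
        0.4822446824578568,
        0.002998231397933124,
        2.0236215049233624e-08,
        0.9999913502914437,
        2.925873030202118e-05,
        0.9999229119352213,
        0.9995600638751996,
        0.9999978341618354,
        0.9980652383540529,
        4.2220925734307325e-05,
        0.6421333935333047,
        9.496193035340021e-05,
        8.074159624102961,
        138.1723060597229,
    ),
    "mid": (
        -86.29492899611243,
        0.001367559671906051,
        0.7729235691987899,
        0.7729125881470815,
        0.00018160055955371553,
        0.4822462587356085,
        0.0029981990442527313,
        2.0235704042826676e-08,
        0.9999982553836957,
        2.9258139245787017e-05,
        0.9999229136040233,
        0.9995600733920637,
        0.9999978342101254,
        0.9980652589598056,
        4.222084778615137e-05,
        0.6421316418825124,
        9.496087155861984e-05,
        8.074168007955082,
        138.17229871626284,
    ),
    "epi": (
        -86.29477748792254,
        0.0013676038662407293,
        0.772919760021505,
        0.7729087784238873,
        0.00018160448975891382,
        0.48224468251361435,
        0.002998231396788526,
        2.0236215031157487e-08,
        0.999998255330828,
        2.9258730281113576e-05,
        0.9999229119352803,
        0.9995600638755364,
        0.9999978341618372,
        0.9980652383547824,
        4.222092573110757e-05,
        0.6421333934519488,
        9.4961930315432e-05,
        8.074159624517447,
        138.1723060593602,
    ),
}
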