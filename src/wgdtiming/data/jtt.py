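"""JTT amino-acid replacement model (Jones, Taylor & Thornton 1992).

Lower-triangle exchangeabilities and equilibrium frequencies in the
standard PAML state order ``ARNDCQEGHILKMFPSTWYV``.
"""

JTT_STATE_ORDER = "ARNDCQEGHILKMFPSTWYV"

# row-by-row lower triangle: s(R,A), s(N,A), s(N,R), s(D,A), ...
JTT_EXCHANGEABILITIES = (
    58.0, 54.0, 81.0, 56.0, 57.0, 105.0, 179.0, 27.0, 36.0, 30.0,
    35.0, 54.0, 15.0, 194.0, 378.0, 475.0, 9.0, 11.0, 298.0, 45.0,
    16.0, 113.0, 310.0, 29.0, 137.0, 328.0, 22.0, 38.0, 646.0, 44.0,
    5.0, 74.0, 101.0, 64.0, 126.0, 20.0, 17.0, 528.0, 34.0, 86.0,
    58.0, 81.0, 391.0, 47.0, 12.0, 263.0, 30.0, 10.0, 15.0, 503.0,
    232.0, 8.0, 70.0, 16.0, 10.0, 49.0, 767.0, 130.0, 112.0, 11.0,
    7.0, 26.0, 15.0, 4.0, 15.0, 59.0, 38.0, 4.0, 46.0, 31.0,
    9.0, 5.0, 59.0, 69.0, 17.0, 23.0, 7.0, 31.0, 78.0, 14.0,
    223.0, 42.0, 115.0, 209.0, 62.0, 323.0, 26.0, 597.0, 9.0, 72.0,
    292.0, 43.0, 4.0, 164.0, 53.0, 51.0, 18.0, 24.0, 20.0, 119.0,
    26.0, 12.0, 9.0, 181.0, 18.0, 5.0, 18.0, 30.0, 32.0, 10.0,
    7.0, 45.0, 23.0, 6.0, 6.0, 27.0, 14.0, 5.0, 24.0, 201.0,
    33.0, 55.0, 8.0, 47.0, 16.0, 56.0, 45.0, 33.0, 40.0, 115.0,
    73.0, 46.0, 8.0, 573.0, 11.0, 229.0, 21.0, 479.0, 89.0, 10.0,
    40.0, 245.0, 9.0, 32.0, 961.0, 14.0, 388.0, 248.0, 102.0, 59.0,
    25.0, 52.0, 24.0, 180.0, 65.0, 4.0, 21.0, 47.0, 103.0, 10.0,
    8.0, 14.0, 43.0, 16.0, 29.0, 226.0, 24.0, 18.0, 323.0, 17.0,
    92.0, 12.0, 53.0, 536.0, 62.0, 285.0, 118.0, 6.0, 10.0, 23.0,
    477.0, 35.0, 63.0, 38.0, 12.0, 21.0, 112.0, 71.0, 25.0, 16.0,
)

JTT_FREQUENCIES = (
    0.07674792325, 0.05169094831, 0.04264495736, 0.05154394846, 0.0198029802,
    0.04075195925, 0.06182993817, 0.07315192685, 0.02294397706, 0.05376094624,
    0.0919039081, 0.05867594132, 0.02382597617, 0.04012595987, 0.0509009491,
    0.06876493124, 0.05856494144, 0.01426098574, 0.0321019679, 0.066004934,
)
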