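"""Independent straight-line transcription of the RULA worksheet.

Used as the oracle for the vectorised engine: every step is written as a
plain if/elif walk over the printed worksheet, and the three lookup tables
are encoded cell by cell in a different layout than the implementation.
Deliberately unclever; do not import from rulatime here beyond thresholds.
"""

# Table A rows keyed by (upper_arm, lower_arm); per wrist posture 1-4 the
# pair (twist 1, twist 2).
ORACLE_TABLE_A = {
    (1, 1): [(1, 2), (2, 2), (2, 3), (3, 3)],
    (1, 2): [(2, 2), (2, 2), (3, 3), (3, 3)],
    (1, 3): [(2, 3), (3, 3), (3, 3), (4, 4)],
    (2, 1): [(2, 3), (3, 3), (3, 4), (4, 4)],
    (2, 2): [(3, 3), (3, 3), (3, 4), (4, 4)],
    (2, 3): [(3, 4), (4, 4), (4, 4), (5, 5)],
    (3, 1): [(3, 3), (4, 4), (4, 4), (5, 5)],
    (3, 2): [(3, 4), (4, 4), (4, 4), (5, 5)],
    (3, 3): [(4, 4), (4, 4), (4, 5), (5, 5)],
    (4, 1): [(4, 4), (4, 4), (4, 5), (5, 5)],
    (4, 2): [(4, 4), (4, 4), (4, 5), (5, 5)],
    (4, 3): [(4, 4), (4, 5), (5, 5), (6, 6)],
    (5, 1): [(5, 5), (5, 5), (5, 6), (6, 7)],
    (5, 2): [(5, 6), (6, 6), (6, 7), (7, 7)],
    (5, 3): [(6, 6), (6, 7), (7, 7), (7, 8)],
    (6, 1): [(7, 7), (7, 7), (7, 8), (8, 9)],
    (6, 2): [(8, 8), (8, 8), (8, 9), (9, 9)],
    (6, 3): [(9, 9), (9, 9), (9, 9), (9, 9)],
}

# Table B rows keyed by neck score; per trunk score 1-6 the pair
# (legs 1, legs 2).
ORACLE_TABLE_B = {
    1: [(1, 3), (2, 3), (3, 4), (5, 5), (6, 6), (7, 7)],
    2: [(2, 3), (2, 3), (4, 5), (5, 5), (6, 7), (7, 7)],
    3: [(3, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 7)],
    4: [(5, 5), (5, 6), (6, 7), (7, 7), (7, 7), (8, 8)],
    5: [(7, 7), (7, 7), (7, 8), (8, 8), (8, 8), (8, 8)],
    6: [(8, 8), (8, 8), (8, 8), (8, 9), (9, 9), (9, 9)],
}

# Table C rows keyed by (saturated) score C 1-8; columns score D 1-7.
ORACLE_TABLE_C = {
    1: (1, 2, 3, 3, 4, 5, 5),
    2: (2, 2, 3, 4, 4, 5, 5),
    3: (3, 3, 3, 4, 4, 5, 6),
    4: (3, 3, 3, 4, 5, 6, 6),
    5: (4, 4, 4, 5, 6, 7, 7),
    6: (4, 4, 5, 6, 6, 7, 7),
    7: (5, 5, 6, 6, 7, 7, 7),
    8: (5, 5, 6, 7, 7, 7, 7),
}


def oracle_upper_arm(flexion, abducted=False, raised=False, supported=False):
    if -20.0 <= flexion <= 20.0:
        s = 1
    elif flexion < -20.0:
        s = 2
    elif flexion <= 45.0:
        s = 2
    elif flexion <= 90.0:
        s = 3
    else:
        s = 4
    if raised:
        s = s + 1
    if abducted:
        s = s + 1
    if supported:
        s = s - 1
    if s < 1:
        s = 1
    if s > 6:
        s = 6
    return s


def oracle_lower_arm(flexion, across=False):
    if 60.0 <= flexion <= 100.0:
        s = 1
    else:
        s = 2
    if across:
        s = s + 1
    if s > 3:
        s = 3
    return s


def oracle_wrist(flexion, deviation, endrange=False, neutral=1.0, dev_thr=10.0):
    mag = flexion if flexion >= 0 else -flexion
    if mag <= neutral:
        p = 1
    elif mag <= 15.0:
        p = 2
    else:
        p = 3
    if deviation > dev_thr:
        p = p + 1
    if p > 4:
        p = 4
    t = 2 if endrange else 1
    return p, t, p + t


def oracle_neck(flexion, rotation=0.0, side=0.0, twist_thr=10.0, side_thr=10.0):
    if flexion < 0.0:
        s = 4
    elif flexion <= 10.0:
        s = 1
    elif flexion <= 20.0:
        s = 2
    else:
        s = 3
    if abs(rotation) > twist_thr:
        s = s + 1
    if abs(side) > side_thr:
        s = s + 1
    if s > 6:
        s = 6
    return s


def oracle_trunk(flexion, rotation=0.0, side=0.0, supported=False,
                 neutral=5.0, twist_thr=10.0, side_thr=10.0):
    if supported and -neutral <= flexion <= neutral:
        s = 1
    elif flexion <= 20.0:
        s = 2
    elif flexion <= 60.0:
        s = 3
    else:
        s = 4
    if abs(rotation) > twist_thr:
        s = s + 1
    if abs(side) > side_thr:
        s = s + 1
    if s > 6:
        s = 6
    return s


def oracle_legs(supported=True):
    return 1 if supported else 2


def oracle_table_a(ua, la, wp, wt):
    return ORACLE_TABLE_A[(ua, la)][wp - 1][wt - 1]


def oracle_table_b(neck, trunk, legs):
    return ORACLE_TABLE_B[neck][trunk - 1][legs - 1]


def oracle_table_c(sc, sd):
    if sc > 8:
        sc = 8
    if sd > 7:
        sd = 7
    return ORACLE_TABLE_C[sc][sd - 1]


def oracle_score_frame(frame, side="r", muscle_a=0, muscle_b=0,
                       force_a=0, force_b=0, abduction_thr=45.0):
    sfx = "_" + side
    abducted = frame.get(
        "arm_abducted_flag" + sfx,
        frame["upper_arm_abduction" + sfx] > abduction_thr,
    )
    ua = oracle_upper_arm(
        frame["upper_arm_flexion" + sfx],
        abducted=bool(abducted),
        raised=bool(frame["shoulder_raise_flag" + sfx]),
        supported=bool(frame["arm_supported_flag" + sfx]),
    )
    la = oracle_lower_arm(
        frame["lower_arm_flexion" + sfx], bool(frame["arm_across_midline_flag" + sfx])
    )
    wp, wt, wc = oracle_wrist(
        frame["wrist_flexion" + sfx],
        frame["wrist_deviation" + sfx],
        bool(frame["wrist_twist_endrange_flag" + sfx]),
    )
    neck = oracle_neck(
        frame["neck_flexion"], frame["neck_rotation"], frame["neck_side_bend"]
    )
    trunk = oracle_trunk(
        frame["trunk_flexion"], frame["trunk_rotation"], frame["trunk_side_bend"],
        bool(frame["trunk_supported_flag"]),
    )
    legs = oracle_legs(bool(frame["legs_supported_flag"]))
    ta = oracle_table_a(ua, la, wp, wt)
    tb = oracle_table_b(neck, trunk, legs)
    sc = ta + muscle_a + force_a
    sd = tb + muscle_b + force_b
    return {
        "upper_arm": ua, "lower_arm": la, "wrist_posture": wp, "wrist_twist": wt,
        "wrist_combined": wc, "table_a": ta, "neck": neck, "trunk": trunk,
        "legs": legs, "table_b": tb, "score_c": sc, "score_d": sd,
        "final": oracle_table_c(sc, sd),
    }
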