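"""Double Metaphone phonetic encoder.

Implements Lawrence Philips' Double Metaphone algorithm: every word maps to
a primary code and an alternate code capturing a plausible second
pronunciation (Anglo vs. continental readings of the same spelling).  Codes
are truncated to 4 characters, the algorithm's common default.  The encoder
is written from the published rule set; no third-party library is involved.
"""

from __future__ import annotations

VOWELS = "AEIOUY"


def _is_vowel(s: str, pos: int) -> bool:
    return 0 <= pos < len(s) and s[pos] in VOWELS


def _string_at(s: str, start: int, length: int, options) -> bool:
    if start < 0 or start >= len(s):
        return False
    return s[start:start + length] in options


def _is_slavo_germanic(s: str) -> bool:
    return any(t in s for t in ("W", "K", "CZ", "WITZ"))


def double_metaphone(word: str, max_length: int = 4) -> tuple[str, str]:
    """Return (primary, alternate) codes; alternate == primary when no
    alternative pronunciation exists."""
    original = word.upper()
    s = original + "     "
    length = len(original)
    last = length - 1
    slavo = _is_slavo_germanic(original)

    primary: list[str] = []
    secondary: list[str] = []

    def add(p: str, sec: str | None = None) -> None:
        primary.append(p)
        secondary.append(p if sec is None else sec)

    current = 0
    # silent initial letters
    if _string_at(s, 0, 2, ("GN", "KN", "PN", "WR", "PS")):
        current = 1
    # initial X is pronounced Z, encoded S (e.g. Xavier)
    if s[0] == "X":
        add("S")
        current = 1

    while current < length:
        if len("".join(primary)) >= max_length and len("".join(secondary)) >= max_length:
            break
        c = s[current]

        if c in VOWELS:
            if current == 0:
                add("A")
            current += 1

        elif c == "B":
            add("P")
            current += 2 if s[current + 1] == "B" else 1

        elif c == "\xc7":  # Ç
            add("S")
            current += 1

        elif c == "C":
            # germanic ACH but not BACHER / MACHER style
            if (current > 1 and not _is_vowel(s, current - 2)
                    and _string_at(s, current - 1, 3, ("ACH",))
                    and s[current + 2] != "I"
                    and (s[current + 2] != "E"
                         or _string_at(s, current - 2, 6, ("BACHER", "MACHER")))):
                add("K")
                current += 2
            elif current == 0 and _string_at(s, 0, 6, ("CAESAR",)):
                add("S")
                current += 2
            elif _string_at(s, current, 4, ("CHIA",)):  # italian chianti
                add("K")
                current += 2
            elif _string_at(s, current, 2, ("CH",)):
                if current > 0 and _string_at(s, current, 4, ("CHAE",)):
                    add("K", "X")  # michael
                    current += 2
                elif (current == 0
                      and (_string_at(s, current + 1, 5, ("HARAC", "HARIS"))
                           or _string_at(s, current + 1, 3,
                                         ("HOR", "HYM", "HIA", "HEM")))
                      and not _string_at(s, 0, 5, ("CHORE",))):
                    add("K")  # greek roots: chorus, chemistry ...
                    current += 2
                elif ((_string_at(s, 0, 4, ("VAN ", "VON "))
                       or _string_at(s, 0, 3, ("SCH",)))
                      or _string_at(s, current - 2, 6,
                                    ("ORCHES", "ARCHIT", "ORCHID"))
                      or _string_at(s, current + 2, 1, ("T", "S"))
                      or ((current == 0
                           or _string_at(s, current - 1, 1, ("A", "O", "U", "E")))
                          and _string_at(s, current + 2, 1,
                                         ("L", "R", "N", "M", "B", "H", "F",
                                          "V", "W", " ")))):
                    add("K")  # germanic / greek / 'architect' but not 'arch'
                    current += 2
                else:
                    if current > 0:
                        if _string_at(s, 0, 2, ("MC",)):
                            add("K")  # McHugh
                        else:
                            add("X", "K")
                    else:
                        add("X")
                    current += 2
            elif (_string_at(s, current, 2, ("CZ",))
                  and not _string_at(s, current - 2, 4, ("WICZ",))):
                add("S", "X")
                current += 2
            elif _string_at(s, current + 1, 3, ("CIA",)):  # focaccia
                add("X")
                current += 3
            elif (_string_at(s, current, 2, ("CC",))
                  and not (current == 1 and s[0] == "M")):
                # double C as X but not McClellan
                if (_string_at(s, current + 2, 1, ("I", "E", "H"))
                        and not _string_at(s, current + 2, 2, ("HU",))):
                    if ((current == 1 and s[current - 1] == "A")
                            or _string_at(s, current - 1, 5, ("UCCEE", "UCCES"))):
                        add("KS")  # accident, accede, succeed
                    else:
                        add("X")  # bacci, bertucci
                    current += 3
                else:
                    add("K")  # Pierce's rule
                    current += 2
            elif _string_at(s, current, 2, ("CK", "CG", "CQ")):
                add("K")
                current += 2
            elif _string_at(s, current, 2, ("CI", "CE", "CY")):
                if _string_at(s, current, 3, ("CIO", "CIE", "CIA")):
                    add("S", "X")  # italian vs. english
                else:
                    add("S")
                current += 2
            else:
                add("K")
                if _string_at(s, current + 1, 2, (" C", " Q", " G")):
                    current += 3  # mac caffrey, mac gregor
                elif (_string_at(s, current + 1, 1, ("C", "K", "Q"))
                      and not _string_at(s, current + 1, 2, ("CE", "CI"))):
                    current += 2
                else:
                    current += 1

        elif c == "D":
            if _string_at(s, current, 2, ("DG",)):
                if _string_at(s, current + 2, 1, ("I", "E", "Y")):
                    add("J")  # edge
                    current += 3
                else:
                    add("TK")  # edgar
                    current += 2
            elif _string_at(s, current, 2, ("DT", "DD")):
                add("T")
                current += 2
            else:
                add("T")
                current += 1

        elif c == "F":
            add("F")
            current += 2 if s[current + 1] == "F" else 1

        elif c == "G":
            if s[current + 1] == "H":
                if current > 0 and not _is_vowel(s, current - 1):
                    add("K")
                    current += 2
                elif current == 0:
                    if s[current + 2] == "I":
                        add("J")  # ghislane
                    else:
                        add("K")  # ghost
                    current += 2
                # Parker's rule (with further refinements): silent GH
                elif ((current > 1 and _string_at(s, current - 2, 1, ("B", "H", "D")))
                      or (current > 2 and _string_at(s, current - 3, 1, ("B", "H", "D")))
                      or (current > 3 and _string_at(s, current - 4, 1, ("B", "H")))):
                    current += 2
                else:
                    if (current > 2 and s[current - 1] == "U"
                            and _string_at(s, current - 3, 1,
                                           ("C", "G", "L", "R", "T"))):
                        add("F")  # laugh, cough, rough, tough
                    elif current > 0 and s[current - 1] != "I":
                        add("K")
                    current += 2
            elif s[current + 1] == "N":
                if current == 1 and _is_vowel(s, 0) and not slavo:
                    add("KN", "N")
                elif (not _string_at(s, current + 2, 2, ("EY",))
                      and s[current + 1] != "Y" and not slavo):
                    add("N", "KN")
                else:
                    add("KN")
                current += 2
            elif _string_at(s, current + 1, 2, ("LI",)) and not slavo:
                add("KL", "L")  # tagliaro
                current += 2
            elif (current == 0
                  and (s[current + 1] == "Y"
                       or _string_at(s, current + 1, 2,
                                     ("ES", "EP", "EB", "EL", "EY", "IB",
                                      "IL", "IN", "IE", "EI", "ER")))):
                add("K", "J")  # -ges-, -gep- etc. at start
                current += 2
            elif ((_string_at(s, current + 1, 2, ("ER",))
                   or s[current + 1] == "Y")
                  and not _string_at(s, 0, 6, ("DANGER", "RANGER", "MANGER"))
                  and not _string_at(s, current - 1, 1, ("E", "I"))
                  and not _string_at(s, current - 1, 3, ("RGY", "OGY"))):
                add("K", "J")  # -ger-, -gy-
                current += 2
            elif (_string_at(s, current + 1, 1, ("E", "I", "Y"))
                  or _string_at(s, current - 1, 4, ("AGGI", "OGGI"))):
                if (_string_at(s, 0, 4, ("VAN ", "VON "))
                        or _string_at(s, 0, 3, ("SCH",))
                        or _string_at(s, current + 1, 2, ("ET",))):
                    add("K")  # obvious germanic
                elif _string_at(s, current + 1, 4, ("IER ",)):
                    add("J")
                else:
                    add("J", "K")
                current += 2
            else:
                add("K")
                current += 2 if s[current + 1] == "G" else 1

        elif c == "H":
            # keep only if first or between vowels
            if (current == 0 or _is_vowel(s, current - 1)) and _is_vowel(s, current + 1):
                add("H")
                current += 2
            else:
                current += 1

        elif c == "J":
            if _string_at(s, current, 4, ("JOSE",)) or _string_at(s, 0, 4, ("SAN ",)):
                # Jose / San Jacinto: spanish pronunciation
                if ((current == 0 and s[current + 4] == " ")
                        or _string_at(s, 0, 4, ("SAN ",))):
                    add("H")
                else:
                    add("J", "H")  # Yankelovich/Jankelowicz
                current += 1
            elif current == 0 and not _string_at(s, current, 4, ("JOSE",)):
                add("J", "A")
                current += 2 if s[current + 1] == "J" else 1
            else:
                if (_is_vowel(s, current - 1) and not slavo
                        and (s[current + 1] == "A" or s[current + 1] == "O")):
                    add("J", "H")
                elif current == last:
                    add("J", "")
                elif (not _string_at(s, current + 1, 1,
                                     ("L", "T", "K", "S", "N", "M", "B", "Z"))
                      and not _string_at(s, current - 1, 1, ("S", "K", "L"))):
                    add("J")
                current += 2 if s[current + 1] == "J" else 1

        elif c == "K":
            add("K")
            current += 2 if s[current + 1] == "K" else 1

        elif c == "L":
            if s[current + 1] == "L":
                # spanish -illo / -illa / -alle
                if ((current == length - 3
                     and _string_at(s, current - 1, 4, ("ILLO", "ILLA", "ALLE")))
                        or ((_string_at(s, last - 1, 2, ("AS", "OS"))
                             or _string_at(s, last, 1, ("A", "O")))
                            and _string_at(s, current - 1, 4, ("ALLE",)))):
                    add("L", "")
                    current += 2
                else:
                    add("L")
                    current += 2
            else:
                add("L")
                current += 1

        elif c == "M":
            add("M")
            if ((_string_at(s, current - 1, 3, ("UMB",))
                 and (current + 1 == last
                      or _string_at(s, current + 2, 2, ("ER",))))
                    or s[current + 1] == "M"):
                current += 2
            else:
                current += 1

        elif c == "N":
            add("N")
            current += 2 if s[current + 1] == "N" else 1

        elif c == "\xd1":  # Ñ
            add("N")
            current += 1

        elif c == "P":
            if s[current + 1] == "H":
                add("F")
                current += 2
            else:
                add("P")
                current += 2 if _string_at(s, current + 1, 1, ("P", "B")) else 1

        elif c == "Q":
            add("K")
            current += 2 if s[current + 1] == "Q" else 1

        elif c == "R":
            # french e.g. 'rogier', exclude 'hochmeier'
            if (current == last and not slavo
                    and _string_at(s, current - 2, 2, ("IE",))
                    and not _string_at(s, current - 4, 2, ("ME", "MA"))):
                add("", "R")
            else:
                add("R")
            current += 2 if s[current + 1] == "R" else 1

        elif c == "S":
            if _string_at(s, current - 1, 3, ("ISL", "YSL")):
                current += 1  # island, isle
            elif current == 0 and _string_at(s, current, 5, ("SUGAR",)):
                add("X", "S")
                current += 1
            elif _string_at(s, current, 2, ("SH",)):
                if _string_at(s, current + 1, 4,
                              ("HEIM", "HOEK", "HOLM", "HOLZ")):
                    add("S")  # germanic
                else:
                    add("X")
                current += 2
            elif (_string_at(s, current, 3, ("SIO", "SIA"))
                  or _string_at(s, current, 4, ("SIAN",))):
                add("S", "S" if slavo else "X")
                current += 3
            elif ((current == 0
                   and _string_at(s, current + 1, 1, ("M", "N", "L", "W")))
                  or _string_at(s, current + 1, 1, ("Z",))):
                # german & anglicisations: smith -> XMT, snider -> XNTR
                add("S", "X")
                current += 2 if _string_at(s, current + 1, 1, ("Z",)) else 1
            elif _string_at(s, current, 2, ("SC",)):
                if s[current + 2] == "H":
                    if _string_at(s, current + 3, 2,
                                  ("OO", "ER", "EN", "UY", "ED", "EM")):
                        # dutch origin: school, schooner
                        if _string_at(s, current + 3, 2, ("ER", "EN")):
                            add("X", "SK")  # schermerhorn, schenker
                        else:
                            add("SK")
                        current += 3
                    else:
                        if (current == 0 and not _is_vowel(s, 3)
                                and s[3] != "W"):
                            add("X", "S")
                        else:
                            add("X")
                        current += 3
                elif _string_at(s, current + 2, 1, ("I", "E", "Y")):
                    add("S")
                    current += 3
                else:
                    add("SK")
                    current += 3
            else:
                if (current == last
                        and _string_at(s, current - 2, 2, ("AI", "OI"))):
                    add("", "S")  # french: resnais, artois
                else:
                    add("S")
                current += 2 if _string_at(s, current + 1, 1, ("S", "Z")) else 1

        elif c == "T":
            if _string_at(s, current, 4, ("TION",)):
                add("X")
                current += 3
            elif _string_at(s, current, 3, ("TIA", "TCH")):
                add("X")
                current += 3
            elif (_string_at(s, current, 2, ("TH",))
                  or _string_at(s, current, 3, ("TTH",))):
                if (_string_at(s, current + 2, 2, ("OM", "AM"))
                        or _string_at(s, 0, 4, ("VAN ", "VON "))
                        or _string_at(s, 0, 3, ("SCH",))):
                    add("T")  # thomas, thames, germanic
                else:
                    add("0", "T")
                current += 2
            else:
                add("T")
                current += 2 if _string_at(s, current + 1, 1, ("T", "D")) else 1

        elif c == "V":
            add("F")
            current += 2 if s[current + 1] == "V" else 1

        elif c == "W":
            if _string_at(s, current, 2, ("WR",)):
                add("R")
                current += 2
            else:
                if (current == 0
                        and (_is_vowel(s, current + 1)
                             or _string_at(s, current, 2, ("WH",)))):
                    if _is_vowel(s, current + 1):
                        add("A", "F")  # wasserman
                    else:
                        add("A")  # whittier etc. need 'Uomo' match
                if ((current == last and _is_vowel(s, current - 1))
                        or _string_at(s, current - 1, 5,
                                      ("EWSKI", "EWSKY", "OWSKI", "OWSKY"))
                        or _string_at(s, 0, 3, ("SCH",))):
                    add("", "F")  # arnow, polish -owski
                    current += 1
                elif _string_at(s, current, 4, ("WICZ", "WITZ")):
                    add("TS", "FX")
                    current += 4
                else:
                    current += 1

        elif c == "X":
            # french: breaux — final X silent after AU/OU
            if not (current == last
                    and (_string_at(s, current - 3, 3, ("IAU", "EAU"))
                         or _string_at(s, current - 2, 2, ("AU", "OU")))):
                add("KS")
            current += 2 if _string_at(s, current + 1, 1, ("C", "X")) else 1

        elif c == "Z":
            if s[current + 1] == "H":
                add("J")  # chinese pinyin: zhao
                current += 2
            else:
                if (_string_at(s, current + 1, 2, ("ZO", "ZI", "ZA"))
                        or (slavo and current > 0 and s[current - 1] != "T")):
                    add("S", "TS")
                else:
                    add("S")
                current += 2 if s[current + 1] == "Z" else 1

        else:
            current += 1

    p = "".join(primary)[:max_length]
    a = "".join(secondary)[:max_length]
    if not a:
        a = p
    return p, a
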