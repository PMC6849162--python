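{
  "version": 1,
  "language": "pt-BR",
  "description": "Ordered grapheme-to-phoneme rewrite rules for Brazilian Portuguese. First applicable rule wins; 'pattern' is matched at the cursor, 'prev'/'next' constrain the neighbouring letters of the source word ('start'/'end' mark word boundaries, 'vowel'/'consonant' letter classes, or '|'-separated literal letters). 'emit' lists zero or more phoneme symbols. After a run of one repeated letter, the repeats collapse into a single application.",
  "vowel_symbols": ["A", "E", "I", "O", "U"],
  "rules": [
    {"pattern": "ch", "emit": ["SH"]},
    {"pattern": "lh", "emit": ["LH"]},
    {"pattern": "nh", "emit": ["NH"]},
    {"pattern": "ss", "emit": ["S"]},
    {"pattern": "rr", "emit": ["RR"]},
    {"pattern": "qu", "next": "e|i", "emit": ["K"]},
    {"pattern": "qu", "emit": ["K", "U"]},
    {"pattern": "gu", "next": "e|i", "emit": ["G"]},
    {"pattern": "ç", "emit": ["S"]},
    {"pattern": "c", "next": "e|i", "emit": ["S"]},
    {"pattern": "c", "emit": ["K"]},
    {"pattern": "g", "next": "e|i", "emit": ["J"]},
    {"pattern": "g", "emit": ["G"]},
    {"pattern": "h", "emit": []},
    {"pattern": "x", "prev": "start|consonant", "emit": ["SH"]},
    {"pattern": "x", "emit": ["K", "S"]},
    {"pattern": "s", "prev": "vowel", "next": "vowel", "emit": ["Z"]},
    {"pattern": "s", "emit": ["S"]},
    {"pattern": "z", "next": "end", "emit": ["S"]},
    {"pattern": "z", "emit": ["Z"]},
    {"pattern": "m", "next": "vowel", "emit": ["M"]},
    {"pattern": "m", "emit": ["N"]},
    {"pattern": "n", "next": "vowel", "emit": ["N"]},
    {"pattern": "n", "emit": ["N"]},
    {"pattern": "w", "emit": ["V"]},
    {"pattern": "y", "emit": ["I"]},
    {"pattern": "k", "emit": ["K"]},
    {"pattern": "a", "emit": ["A"]},
    {"pattern": "e", "emit": ["E"]},
    {"pattern": "i", "emit": ["I"]},
    {"pattern": "o", "emit": ["O"]},
    {"pattern": "u", "emit": ["U"]},
    {"pattern": "b", "emit": ["B"]},
    {"pattern": "d", "emit": ["D"]},
    {"pattern": "f", "emit": ["F"]},
    {"pattern": "j", "emit": ["J"]},
    {"pattern": "l", "emit": ["L"]},
    {"pattern": "p", "emit": ["P"]},
    {"pattern": "r", "emit": ["R"]},
    {"pattern": "t", "emit": ["T"]},
    {"pattern": "v", "emit": ["V"]}
  ]
}
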