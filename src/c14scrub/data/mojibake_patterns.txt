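# Mojibake detection patterns, one regular expression per line.
# These cover the replacement character and the sequences produced when
# UTF-8 bytes are decoded as a legacy single-byte encoding (Windows-1252,
# MacRoman): an upper-case A-tilde or inverted-breve/Euro pairs for
# two-byte UTF-8 sequences, and the square-root sign from MacRoman.
# The list is editable: real-world corruption is too diverse to enumerate
# once and for all.
�
√
Ã[^\x00-\x7F]
Â[^\x00-\x7F]
â€.
‚Ä.
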