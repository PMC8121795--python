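{
"first_pl": [
"we",
"us",
"our",
"ours",
"ourselves"
],
"first_sg": [
"i",
"me",
"my",
"mine",
"myself"
],
"second": [
"you",
"your",
"yours",
"yourself",
"yourselves"
],
"third": [
"he",
"him",
"his",
"himself",
"she",
"her",
"hers",
"herself",
"they",
"them",
"their",
"theirs",
"themselves",
"it",
"its",
"itself"
]
}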