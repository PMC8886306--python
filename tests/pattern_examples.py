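"""Cross-language rule-coverage examples for the six error patterns.

Each row: (language, pattern, orthographic word, target SAMPA, expected
misarticulated SAMPA). The expected forms correspond segmentally to
published child productions illustrating each pattern; prosody is
preserved. A handful of published illustrations contain an extra process
on top of the one pattern (e.g. English "umbrella" [ˈbɛlʌ] also reduces
/br/, Swedish "sover" [¹to:vər] stops only the /s/) and are therefore not
representable as single-pattern simulations; they are listed in
NOT_SINGLE_PATTERN for documentation.
"""

TABLE_EXAMPLES = [
    # fronting: velars -> coronals
    ("en", "fronting", "egg", '"Eg', '"Ed'),
    ("en", "fronting", "key", '"ki', '"ti'),
    ("en", "fronting", "back", '"b{k', '"b{t'),
    ("en", "fronting", "king", '"kIN', '"tIn'),
    ("en", "fronting", "go", '"goU', '"doU'),
    ("sv", "fronting", "kaka", '""kA:$ka', '""tA:$ta'),
    ("sv", "fronting", "gul", '"g}:l', '"d}:l'),
    ("sv", "fronting", "gunga", '""g0N$a', '""d0n$a'),
    ("no", "fronting", "kopp", '"kOp', '"tOp'),
    ("no", "fronting", "kan", '"kAn', '"tAn'),
    # backing: coronal (incl. retroflex) stops/nasals -> velars
    ("en", "backing", "two", '"tu', '"ku'),
    ("en", "backing", "puddle", '"pV$d@l', '"pV$g@l'),
    ("en", "backing", "bottle", '"bO$t@l', '"bO$k@l'),
    ("sv", "backing", "matta", '""ma$ta', '""ma$ka'),
    ("no", "backing", "ødelegge", '""2:$d@$%lE$g@', '""2:$g@$%lE$g@'),
    # stopping: fricatives/affricates -> plosives
    ("en", "stopping", "chair", '"tSE@', '"tE@'),
    ("en", "stopping", "suck", '"sVk', '"tVk'),
    ("en", "stopping", "thumb", '"TVm', '"tVm'),
    ("sv", "stopping", "vatten", '"va$t@n', '"ba$t@n'),
    ("sv", "stopping", "kors", '"kOs`', '"kOt`'),
    ("no", "stopping", "hus", '"h}:s', '"h}:t'),
    ("no", "stopping", "lise", '""li:$s@', '""li:$t@'),
    # r-weakening: rhotics -> /j/, onset and coda alike
    ("en", "r_weakening", "red", '"rEd', '"jEd'),
    ("en", "r_weakening", "borrow", '"bO$roU', '"bO$joU'),
    ("sv", "r_weakening", "ramla", '""ram$la', '""jam$la'),
    ("sv", "r_weakening", "bara", '""bA:$ra', '""bA:$ja'),
    ("sv", "r_weakening", "dörr", '"d9r', '"d9j'),
    ("no", "r_weakening", "rød", '"r2:', '"j2:'),
    # weak syllable deletion: the syllable before the stressed one goes
    ("en", "weak_syllable_deletion", "banana", 'b@$"n{$n@', '"n{$n@'),
    ("sv", "weak_syllable_deletion", "potatis", 'pU$"tA:$tIs', '"tA:$tIs'),
    ("no", "weak_syllable_deletion", "rakett", 'ra$"kEt', '"kEt'),
    # cluster reduction, syllable-initial clusters only
    ("en", "cluster_reduction", "bread", '"brEd', '"bEd'),
    ("en", "cluster_reduction", "play", '"pleI', '"peI'),
    ("en", "cluster_reduction", "frog", '"frOg', '"fOg'),
    ("en", "cluster_reduction", "fly", '"flaI', '"faI'),
    ("en", "cluster_reduction", "twice", '"twaIs', '"taIs'),
    ("en", "cluster_reduction", "stop", '"stAp', '"tAp'),
    ("en", "cluster_reduction", "snail", '"sneIl', '"neIl'),
    ("en", "cluster_reduction", "slide", '"slaId', '"saId'),
    ("en", "cluster_reduction", "street", '"strit', '"tit'),
    ("en", "cluster_reduction", "splash", '"spl{S', '"p{S'),
    ("sv", "cluster_reduction", "klocka", '""klO$ka', '""kO$ka'),
    ("sv", "cluster_reduction", "frysa", '""fry:$sa', '""fy:$sa'),
    ("sv", "cluster_reduction", "brun", '"br}:n', '"b}:n'),
    ("sv", "cluster_reduction", "kväll", '"kvEl', '"kEl'),
    ("sv", "cluster_reduction", "kniv", '"kni:v', '"ki:v'),
    ("sv", "cluster_reduction", "stol", '"stu:l', '"tu:l'),
    ("sv", "cluster_reduction", "snö", '"sn2:', '"n2:'),
    ("sv", "cluster_reduction", "slåss", '"slOs', '"lOs'),
    ("sv", "cluster_reduction", "svans", '"svans', '"vans'),
    ("sv", "cluster_reduction", "skratta", '""skra$ta', '""ka$ta'),
    ("no", "cluster_reduction", "klippe", '""klI$p@', '""kI$p@'),
    ("no", "cluster_reduction", "trumme", '""trU$m@', '""tU$m@'),
    ("no", "cluster_reduction", "kniv", '"kni:v', '"ki:v'),
    ("no", "cluster_reduction", "sne", '"sne:', '"ne:'),
    ("no", "cluster_reduction", "stol", '"stu:l`', '"tu:l`'),
    ("no", "cluster_reduction", "svale", '""svA:$l@', '""vA:$l@'),
    ("no", "cluster_reduction", "svart", '"svAt`', '"vAt`'),
    ("no", "cluster_reduction", "slange", '""s`l`AN$@', '""l`AN$@'),
]

#: published illustrations showing more than the one simulated pattern
NOT_SINGLE_PATTERN = [
    ("en", "weak_syllable_deletion", "umbrella"),   # also reduces /br/
    ("sv", "weak_syllable_deletion", "leverpastej"),
    ("no", "weak_syllable_deletion", "vaskemaskinen"),
    ("sv", "backing", "tänder"),                    # also drops final /r/
    ("en", "stopping", "face"),                     # stops /f/ but not /s/
    ("sv", "stopping", "sover"),                    # stops /s/ but not /v/
    ("no", "r_weakening", "bærer"),                 # also drops final /r/
    ("sv", "cluster_reduction", "plåster"),         # onset cluster retained
    ("no", "cluster_reduction", "briller"),         # also drops final /r/
]
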