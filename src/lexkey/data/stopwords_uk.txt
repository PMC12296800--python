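# Ukrainian stopword lemmas (curated reconstruction).
# One lemma per line; '#' starts a comment. The list complements the
# closed-class UPOS filter (PUNCT, ADP, PRON, CCONJ, SCONJ, PART, DET, AUX)
# and catches function lemmas that taggers sometimes label as open-class.
і
й
та
але
а
або
чи
що
щоб
як
якщо
коли
бо
тому
це
цей
той
такий
весь
кожний
я
ти
він
вона
воно
ми
ви
вони
себе
свій
мій
твій
наш
ваш
їхній
хто
який
котрий
у
в
на
з
із
зі
до
від
по
за
під
над
при
про
без
для
через
між
край
бути
б
би
ж
же
не
ні
ані
так
то
вже
ще
тільки
лише
навіть
ось
он
хіба
нехай
хай
аж
майже
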