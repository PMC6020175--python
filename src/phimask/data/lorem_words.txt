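# Fixed pseudo-Latin filler lexicon. Shipping the lexicon in-repo keeps the
# benchmark's false-positive universe reproducible across machines. The list
# is deliberately NOT filtered for similarity to the address wordlists:
# chance collisions with PHI vocabulary are part of what the benchmark
# measures.
lorem
ipsum
dolor
sit
amet
consectetur
adipiscing
elit
sed
do
eiusmod
tempor
incididunt
ut
labore
et
dolore
magna
aliqua
enim
ad
minim
veniam
quis
nostrud
exercitation
ullamco
laboris
nisi
aliquip
ex
ea
commodo
consequat
duis
aute
irure
in
reprehenderit
voluptate
velit
esse
cillum
eu
fugiat
nulla
pariatur
excepteur
sint
occaecat
cupidatat
non
proident
sunt
culpa
qui
officia
deserunt
mollit
anim
id
est
laborum
at
vero
eos
accusamus
iusto
odio
dignissimos
ducimus
blanditiis
praesentium
voluptatum
deleniti
atque
corrupti
quos
dolores
quas
molestias
excepturi
occaecati
cupiditate
provident
similique
mollitia
animi
distinctio
nam
libero
tempore
cum
soluta
nobis
eligendi
optio
cumque
nihil
impedit
quo
minus
quod
maxime
placeat
facere
possimus
omnis
voluptas
assumenda
repellendus
temporibus
autem
quibusdam
officiis
debitis
rerum
necessitatibus
saepe
eveniet
voluptates
repudiandae
recusandae
itaque
earum
hic
tenetur
sapiente
delectus
reiciendis
voluptatibus
maiores
alias
perferendis
doloribus
asperiores
repellat
curabitur
vivamus
fusce
aenean
mauris
morbi
nunc
nullam
orci
varius
natoque
penatibus
magnis
dis
parturient
montes
nascetur
ridiculus
mus
donec
quam
felis
ultricies
nec
pellentesque
pretium
integer
tincidunt
cras
dapibus
elementum
semper
nisl
aliquet
sollicitudin
lobortis
augue
vitae
sapien
ligula
porttitor
volutpat
maecenas
tristique
senectus
netus
malesuada
fames
turpis
egestas
etiam
feugiat
pharetra
condimentum
vestibulum
ante
primis
faucibus
luctus
ultrices
posuere
cubilia
curae
iaculis
hendrerit
ornare
viverra
fermentum
lacinia
venenatis
rutrum
accumsan
suscipit
cursus
dictum
gravida
laoreet
lacus
suspendisse
potenti
scelerisque
interdum
porta
mattis
aliquam
erat
eleifend
sodales
urna
auctor
arcu
bibendum
imperdiet
euismod
tortor
rhoncus
convallis
vulputate
congue
facilisis
blandit
vehicula
habitant
proin
fringilla
mi
consequuntur
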